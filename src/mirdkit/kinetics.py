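"""Time–activity curve handling and residence-time (TIAC) computation.

An organ's kinetics are represented as a sampled :class:`TimeActivityCurve`
(fraction of injected activity, FIA, or a concentration in kBq/mL) and
modelled as a nonnegative sum of exponentials fitted in the decay-corrected
domain.  Integration to the time-integrated activity coefficient (TIAC,
a.k.a. residence time or normalized number of disintegrations, in hours)
applies physical decay analytically, so decay enters exactly once.

The urinary bladder is treated with a dynamic voiding model: renally
excreted activity fills the bladder, which is emptied instantaneously and
completely at a fixed voiding interval.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import least_squares, nnls

from .nuclide import Nuclide

__all__ = [
    "TimeActivityCurve",
    "ExponentialModel",
    "ResidenceTimeSet",
    "BladderModelParams",
    "decay_correct",
    "fit_sum_of_exponentials",
    "fit_bladder_filling",
    "compute_tiac",
    "bladder_tiac",
    "remainder_of_body_tiac",
    "compute_suv",
]

Units = Literal["FIA", "kBq/mL"]


@dataclass
class TimeActivityCurve:
    """Sampled activity of one organ (or blood/plasma) versus time.

    Parameters
    ----------
    organ
        Organ or sample label.
    times
        Mid-frame sample times, minutes post-injection; strictly increasing, ≥ 0.
    values
        Activity at each time, nonnegative; either fraction of injected
        activity (``units="FIA"``) or concentration (``units="kBq/mL"``).
    units
        Units tag, ``"FIA"`` or ``"kBq/mL"``.
    decay_corrected
        Whether physical decay has been removed from ``values``.
    frame_durations
        Optional acquisition duration per sample, seconds.
    """

    organ: str
    times: np.ndarray
    values: np.ndarray
    units: Units = "FIA"
    decay_corrected: bool = True
    frame_durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise ValueError(f"{self.organ}: times must be strictly increasing and >= 0")
        if np.any(self.values < 0):
            raise ValueError(f"{self.organ}: values must be nonnegative")
        if self.units not in ("FIA", "kBq/mL"):
            raise ValueError(f"unknown units tag {self.units!r}")
        if self.frame_durations is not None:
            self.frame_durations = np.asarray(self.frame_durations, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ExponentialModel:
    """Nonnegative sum of exponentials  A(t) = Σ_i A_i · exp(−λ_i t).

    Amplitudes carry the units of the fitted curve; rates are 1/min.
    ``domain_decay_corrected`` records whether the model describes the
    decay-corrected curve (physical decay must then be added analytically
    when integrating) or the raw physical curve.
    """

    terms: list[tuple[float, float]]  # (amplitude, rate 1/min)
    domain_decay_corrected: bool = True
    units: Units = "FIA"
    organ: str = ""
    rss: float = float("nan")
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= 3:
            raise ValueError("model must have 1-3 exponential terms")
        for a, lam in self.terms:
            if lam < 0:
                raise ValueError(f"negative rate {lam}")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, lam in self.terms:
            out = out + a * np.exp(-lam * t)
        return out


@dataclass
class ResidenceTimeSet:
    """Normalized number of disintegrations per source organ, in hours."""

    organs: dict[str, float]
    remainder_of_body: float = 0.0

    def __post_init__(self) -> None:
        bad = {k: v for k, v in {**self.organs, "remainder of body": self.remainder_of_body}.items() if v < 0}
        if bad:
            raise ValueError(f"negative residence times: {bad}")

    def total(self) -> float:
        return float(sum(self.organs.values()) + self.remainder_of_body)

    def check_physical_bound(self, nuclide: Nuclide, rtol: float = 1e-9) -> None:
        """Assert Σ TIAC ≤ T_p/ln2 hours (all disintegrations accounted once)."""
        bound = nuclide.mean_life_hours
        if self.total() > bound * (1.0 + rtol):
            raise ValueError(
                f"sum of residence times {self.total():.4f} h exceeds the physical "
                f"mean-life bound {bound:.4f} h for {nuclide.name}"
            )

    def as_mapping(self, include_remainder: bool = True) -> dict[str, float]:
        out = dict(self.organs)
        if include_remainder:
            out["remainder of body"] = self.remainder_of_body
        return out


@dataclass
class BladderModelParams:
    """Parameters of the dynamic urinary-bladder voiding model.

    ``excreted_fraction`` is the fraction of injected activity ultimately
    excreted renally; ``biologic_half_life`` (minutes) sets the excretion
    rate λ_b; the bladder is emptied completely every ``voiding_interval``
    hours.
    """

    voiding_interval: float  # hours; math.inf = never void
    excreted_fraction: float
    biologic_half_life: float  # minutes
    initial_bladder_content: float = 0.0  # FIA at t = 0

    def __post_init__(self) -> None:
        if not self.voiding_interval > 0:
            raise ValueError("voiding_interval must be > 0")
        if not 0.0 <= self.excreted_fraction <= 1.0:
            raise ValueError("excreted_fraction must be in [0, 1]")
        if not self.biologic_half_life > 0:
            raise ValueError("biologic_half_life must be > 0")

    @property
    def biologic_rate(self) -> float:
        """λ_b in 1/min."""
        return math.log(2.0) / self.biologic_half_life


def decay_correct(
    curve: TimeActivityCurve,
    nuclide: Nuclide,
    direction: Literal["correct", "uncorrect"] = "correct",
) -> TimeActivityCurve:
    """Apply or remove physical decay from a sampled curve.

    ``correct`` multiplies each value by exp(λ_p t) (removing physical decay
    to expose biological kinetics); ``uncorrect`` divides.  The decay state
    flag is checked and toggled, so double correction is rejected.
    """
    if direction not in ("correct", "uncorrect"):
        raise ValueError(f"direction must be 'correct' or 'uncorrect', got {direction!r}")
    if direction == "correct" and curve.decay_corrected:
        raise ValueError(f"{curve.organ}: curve is already decay-corrected")
    if direction == "uncorrect" and not curve.decay_corrected:
        raise ValueError(f"{curve.organ}: curve is not decay-corrected")
    factor = np.exp(nuclide.decay_constant * curve.times)
    values = curve.values * factor if direction == "correct" else curve.values / factor
    return replace(curve, values=values, decay_corrected=not curve.decay_corrected)


def _rate_grid(times: np.ndarray) -> np.ndarray:
    """Fixed log-spaced candidate rates spanning the sampled time range.

    Includes λ = 0 so plateaus (e.g. long-term bone retention) are
    representable.  Seedless and deterministic by construction.
    """
    t_max = times[-1]
    t_min = times[times > 0][0] if np.any(times > 0) else t_max / 10.0
    lo = 0.1 / t_max
    hi = 2.0 / t_min
    grid = np.geomspace(lo, hi, 6)
    return np.concatenate(([0.0], grid))


def _fit_fixed_order(times: np.ndarray, values: np.ndarray, n_terms: int) -> tuple[np.ndarray, float]:
    """Best nonnegative LSQ fit with exactly ``n_terms`` terms.

    Multi-start: rate combinations from a fixed log-spaced grid, amplitudes
    by NNLS (variable projection), then joint refinement with bounded
    least squares.  Returns (params [A1..An, lam1..lamn], RSS).
    """
    grid = _rate_grid(times)
    best: tuple[np.ndarray, float] | None = None

    def residuals(p: np.ndarray) -> np.ndarray:
        a, lam = p[:n_terms], p[n_terms:]
        return (a[None, :] * np.exp(-np.outer(times, lam))).sum(axis=1) - values

    for lams in itertools.combinations(grid, n_terms):
        design = np.exp(-np.outer(times, np.asarray(lams)))
        amps, _ = nnls(design, values)
        p0 = np.concatenate([amps, np.asarray(lams)])
        sol = least_squares(
            residuals,
            p0,
            bounds=(np.zeros(2 * n_terms), np.full(2 * n_terms, np.inf)),
            method="trf",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    assert best is not None
    return best


def fit_sum_of_exponentials(curve: TimeActivityCurve, max_terms: int = 3) -> ExponentialModel:
    """Fit a nonnegative sum of exponentials to a sampled curve.

    The model order is selected among 1..``max_terms`` by the nested
    extra-sum-of-squares F-test (α = 0.05): a higher order is kept only
    when its residual reduction is significant, so ties and marginal gains
    resolve toward fewer terms.  Each candidate order needs at least 2·n+1
    samples.  Fitting is deterministic: starts come from a fixed
    log-spaced rate grid.
    """
    from scipy.stats import f as f_dist

    if not 1 <= max_terms <= 3:
        raise ValueError("max_terms must be in 1..3")
    times, values = curve.times, curve.values
    n = len(times)
    if n < 2:
        raise ValueError(f"{curve.organ}: need at least 2 samples, got {n}")
    if np.all(values == 0):
        warnings.warn(f"{curve.organ}: all-zero curve; returning zero model")
        return ExponentialModel(
            [(0.0, 0.0)], curve.decay_corrected, curve.units, curve.organ, 0.0, n
        )

    scale = float(np.max(np.abs(values)))
    rss_floor = n * (1e-12 * scale) ** 2  # numerical-zero floor: exact fits tie
    best_params: np.ndarray | None = None
    best_rss = math.inf
    best_k = 0
    for n_terms in range(1, max_terms + 1):
        k = 2 * n_terms
        if n - k < 1:
            continue
        params, rss = _fit_fixed_order(times, values, n_terms)
        if best_params is None:
            best_params, best_rss, best_k = params, rss, k
            continue
        dk = k - best_k
        f_stat = ((best_rss - rss) / dk) / (max(rss, rss_floor) / (n - k))
        if f_stat > f_dist.ppf(0.95, dk, n - k):
            best_params, best_rss, best_k = params, rss, k
    if best_params is None:
        raise ValueError(
            f"{curve.organ}: too few samples ({n}) for any model order up to {max_terms}"
        )
    m = len(best_params) // 2
    terms = sorted(zip(best_params[:m], best_params[m:]), key=lambda t: t[1])
    # drop numerically-dead duplicate terms (zero amplitude)
    kept = [(float(a), float(l)) for a, l in terms if a > 1e-14 * scale] or [
        (float(terms[0][0]), float(terms[0][1]))
    ]
    return ExponentialModel(kept, curve.decay_corrected, curve.units, curve.organ, best_rss, n)


def compute_tiac(model: ExponentialModel, nuclide: Nuclide) -> float:
    """Time-integrated activity coefficient of a fitted organ model, hours.

    For a decay-corrected FIA model, TIAC = Σ A_i/(λ_i + λ_p) minutes,
    converted to hours — physical decay is applied exactly once,
    analytically.  For a model fitted to raw (physical) data, decay is
    already in the rates and TIAC = Σ A_i/λ_i.
    """
    if model.units != "FIA":
        raise ValueError(
            f"TIAC requires amplitudes in FIA units, got {model.units!r}"
        )
    lam_p = nuclide.decay_constant if model.domain_decay_corrected else 0.0
    total_min = 0.0
    for a, lam in model.terms:
        denom = lam + lam_p
        if denom <= 0:
            if a > 0:
                raise ValueError(
                    f"term (A={a}, lambda={lam}) has no decay at all: integral diverges"
                )
            continue
        total_min += a / denom
    return total_min / 60.0


def bladder_tiac(params: BladderModelParams, nuclide: Nuclide, tol: float = 1e-10) -> float:
    """TIAC of the urinary bladder contents under the dynamic voiding model.

    Decay-corrected bladder content between voids grows as
    f·(e^{−λ_b t_k} − e^{−λ_b t}) from the last void at t_k; the physical
    activity is that content times e^{−λ_p t}; the bladder is emptied
    completely every T_v hours.  The per-cycle integrals are closed-form
    and the cycle series is summed until the increment falls below ``tol``
    of the running total.  T_v = ∞ gives the no-void closed form
    f·λ_b/((λ_b+λ_p)·λ_p).
    """
    lam_b = params.biologic_rate
    lam_p = nuclide.decay_constant
    f = params.excreted_fraction
    b0 = params.initial_bladder_content

    if math.isinf(params.voiding_interval):
        total = f * lam_b / ((lam_b + lam_p) * lam_p) + b0 / lam_p
        return total / 60.0

    tv = params.voiding_interval * 60.0  # minutes
    total = 0.0
    # initial content survives only the first cycle
    total += b0 * (1.0 - math.exp(-lam_p * tv)) / lam_p
    k = 0
    while True:
        t0, t1 = k * tv, (k + 1) * tv
        term = f * (
            math.exp(-lam_b * t0) * (math.exp(-lam_p * t0) - math.exp(-lam_p * t1)) / lam_p
            - (math.exp(-(lam_b + lam_p) * t0) - math.exp(-(lam_b + lam_p) * t1)) / (lam_b + lam_p)
        )
        total += term
        k += 1
        if k > 100000 or (total > 0 and term < tol * total) or term == 0.0:
            break
    return total / 60.0


def fit_bladder_filling(curve: TimeActivityCurve) -> BladderModelParams:
    """Estimate renal excretion parameters from a bladder filling curve.

    Fits B(t) = f·(1 − e^{−λ_b t}) to the decay-corrected bladder FIA
    samples (no voids during the imaging session assumed), returning the
    excreted fraction f and biologic half-life ln2/λ_b.  The voiding
    interval is left at the dosimetry default of 3.5 h.
    """
    if not curve.decay_corrected or curve.units != "FIA":
        raise ValueError("bladder filling fit expects a decay-corrected FIA curve")
    t, y = curve.times, curve.values

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * (1.0 - np.exp(-p[1] * t)) - y

    best = None
    for lam0 in np.geomspace(0.1 / t[-1], 2.0 / max(t[0], 1e-3), 8):
        sol = least_squares(
            resid, [min(1.0, max(y.max(), 1e-6)), lam0],
            bounds=([0.0, 1e-9], [1.0, np.inf]),
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    f, lam_b = best[0]
    return BladderModelParams(
        voiding_interval=3.5,
        excreted_fraction=float(f),
        biologic_half_life=math.log(2.0) / float(lam_b),
    )


def remainder_of_body_tiac(
    whole_body_tiac: float, organ_set: ResidenceTimeSet | Mapping[str, float]
) -> float:
    """Remainder-of-body TIAC = whole-body TIAC − Σ listed source organs.

    The urinary bladder (if listed) participates in the subtraction.
    Raises if the listed organs already exceed the whole-body integral.
    """
    organs = organ_set.organs if isinstance(organ_set, ResidenceTimeSet) else dict(organ_set)
    organ_sum = float(sum(organs.values()))
    remainder = whole_body_tiac - organ_sum
    if remainder < 0:
        raise ValueError(
            f"source organs ({', '.join(sorted(organs))}) sum to {organ_sum:.4f} h, "
            f"exceeding the whole-body TIAC {whole_body_tiac:.4f} h"
        )
    return remainder


def compute_suv(
    concentration_kbq_ml: float | np.ndarray,
    injected_activity_mbq: float,
    body_weight_kg: float,
) -> float | np.ndarray:
    """Standardized uptake value, assuming 1 g/mL tissue density.

    SUV = concentration / (injected activity / body mass)
        = concentration[kBq/mL] · weight[kg] / injected[MBq]
    (the kBq→MBq and kg→g factors of 1000 cancel).
    """
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be > 0")
    conc = np.asarray(concentration_kbq_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    out = conc * body_weight_kg / injected_activity_mbq
    return float(out) if out.ndim == 0 else out
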