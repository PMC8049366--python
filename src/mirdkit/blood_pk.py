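"""Blood-side pharmacokinetics of the tracer.

Covers plasma/whole-blood partitioning, plasma protein binding, the
radio-HPLC parent-fraction curve (metabolite correction), monoexponential
tail fitting, and non-compartmental AUC/clearance.  All pharmacokinetic
evaluation is done on decay-corrected data, so the half-lives and
clearances reported are biologic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .kinetics import TimeActivityCurve

__all__ = [
    "PlasmaSampleSeries",
    "ParentFractionCurve",
    "PKParameters",
    "RatioSummary",
    "plasma_to_blood_ratio",
    "protein_bound_fraction",
    "fit_parent_fraction",
    "metabolite_correct",
    "fit_monoexp_tail",
    "clearance",
]


@dataclass
class PlasmaSampleSeries:
    """Venous sample measurements over the blood-sampling schedule.

    Concentrations are in kBq/mL; ``parent_fraction`` (from radio-HPLC) is
    dimensionless in [0, 1].  ``protein_free_supernatant`` and
    ``parent_fraction`` are optional (NaN marks absent samples).
    """

    times: np.ndarray  # minutes
    whole_blood: np.ndarray
    plasma: np.ndarray
    protein_free_supernatant: np.ndarray | None = None
    parent_fraction: np.ndarray | None = None
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        for name in ("whole_blood", "plasma"):
            arr = getattr(self, name)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
            if np.any(arr[~np.isnan(arr)] < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.protein_free_supernatant is not None:
            self.protein_free_supernatant = np.asarray(self.protein_free_supernatant, float)
        if self.parent_fraction is not None:
            pf = np.asarray(self.parent_fraction, dtype=float)
            ok = ~np.isnan(pf)
            if np.any((pf[ok] < 0) | (pf[ok] > 1)):
                raise ValueError("parent_fraction must lie in [0, 1]")
            self.parent_fraction = pf

    def plasma_curve(self, label: str = "plasma") -> TimeActivityCurve:
        return TimeActivityCurve(
            label, self.times, self.plasma, units="kBq/mL",
            decay_corrected=self.decay_corrected,
        )


@dataclass
class RatioSummary:
    ratios: np.ndarray  # NaN where excluded
    mean: float
    sd: float


def plasma_to_blood_ratio(series: PlasmaSampleSeries) -> RatioSummary:
    """Per-sample plasma/whole-blood activity ratio with mean ± SD.

    Samples with zero whole-blood activity are excluded with a warning;
    if every sample is excluded, an error is raised.
    """
    blood = series.whole_blood
    usable = ~np.isnan(blood) & (blood > 0) & ~np.isnan(series.plasma)
    if not usable.any():
        raise ValueError("no samples with positive whole-blood activity")
    if (~usable).any():
        warnings.warn(f"{int((~usable).sum())} sample(s) excluded from plasma:blood ratio")
    ratios = np.full_like(blood, np.nan)
    ratios[usable] = series.plasma[usable] / blood[usable]
    vals = ratios[usable]
    return RatioSummary(ratios, float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)


def protein_bound_fraction(series: PlasmaSampleSeries, tolerance: float = 0.05) -> np.ndarray:
    """Percentage of plasma radioactivity bound to plasma proteins, per sample.

    bound% = 100·(plasma − protein-free supernatant)/plasma.  A supernatant
    exceeding plasma by more than ``tolerance`` (relative) indicates an
    assay inconsistency and raises; small excesses are clipped to 0%.
    """
    if series.protein_free_supernatant is None:
        raise ValueError("series has no protein-free supernatant measurements")
    plasma, sup = series.plasma, series.protein_free_supernatant
    with np.errstate(invalid="ignore", divide="ignore"):
        excess = (sup - plasma) / np.where(plasma > 0, plasma, np.nan)
    if np.any(excess[~np.isnan(excess)] > tolerance):
        raise ValueError("supernatant exceeds plasma by more than the assay tolerance")
    bound = 100.0 * (plasma - sup) / plasma
    return np.clip(bound, 0.0, 100.0)


@dataclass
class ParentFractionCurve:
    """Monotone nonincreasing parent-fraction model f(t) = A·e^{−k t} + c.

    Evaluation is clipped to [0, 1]; the fit may have A + c slightly above
    1 when anchored to steep early data, in which case the clipped region
    ends before the first sample.  ``support`` records the fitted time range.
    """

    amplitude: float
    rate: float  # 1/min
    plateau: float
    support: tuple[float, float] = (0.0, math.inf)
    residuals: np.ndarray | None = None
    nonmonotone_input: bool = False
    form: str = "exp_plus_plateau"

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.rate < 0 or self.plateau < 0:
            raise ValueError("parent-fraction parameters must be nonnegative")
        if self.plateau > 1:
            raise ValueError("plateau must be <= 1")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.clip(self.amplitude * np.exp(-self.rate * t) + self.plateau, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


def fit_parent_fraction(
    times: np.ndarray, fractions: np.ndarray, fix_plateau: float | None = None
) -> ParentFractionCurve:
    """Fit the single-exponential-plus-plateau parent-fraction model.

    Constrained so the curve is monotone nonincreasing and within [0, 1]
    (by clipping); non-monotone input beyond a 2% tolerance still yields a
    fit but is flagged.  With ``fix_plateau`` the plateau is held fixed
    (the two remaining parameters are exactly determined by two samples).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if len(t) < (2 if fix_plateau is not None else 3):
        raise ValueError("need at least 3 samples (2 with a fixed plateau)")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    nonmono = bool(np.any(np.diff(y) > 0.02))
    if nonmono:
        warnings.warn("parent fractions are non-monotone beyond tolerance; fit flagged")

    if np.ptp(y) < 1e-12:
        return ParentFractionCurve(0.0, 0.0, float(y[0]), (float(t[0]), float(t[-1])),
                                   np.zeros_like(y), nonmono)

    def model(p: np.ndarray) -> np.ndarray:
        a, k = p[0], p[1]
        c = fix_plateau if fix_plateau is not None else p[2]
        return a * np.exp(-k * t) + c

    # rate initial guess from the two extreme samples
    k0 = max(1e-3, math.log(max(y[0], 1e-6) / max(y[-1], 1e-6)) / max(t[-1] - t[0], 1e-9))
    if fix_plateau is not None:
        p0, lo, hi = [y[0], k0], [0.0, 0.0], [2.0, np.inf]
    else:
        p0, lo, hi = [y[0], k0, max(float(y.min()), 0.0)], [0.0, 0.0, 0.0], [2.0, np.inf, 1.0]
    sol = least_squares(lambda p: model(p) - y, p0, bounds=(lo, hi),
                        ftol=1e-15, xtol=1e-15, gtol=1e-15)
    a, k = float(sol.x[0]), float(sol.x[1])
    c = float(fix_plateau if fix_plateau is not None else sol.x[2])
    return ParentFractionCurve(a, k, c, (float(t[0]), float(t[-1])), sol.fun.copy(), nonmono)


def metabolite_correct(
    plasma_tac: TimeActivityCurve, curve: ParentFractionCurve
) -> TimeActivityCurve:
    """Parent-tracer concentration: total plasma activity × f_parent(t) pointwise."""
    parent = plasma_tac.values * np.asarray(curve(plasma_tac.times))
    return replace(plasma_tac, organ=f"{plasma_tac.organ} (parent)", values=parent)


@dataclass
class PKParameters:
    """Tail-fit and non-compartmental pharmacokinetic summary.

    ``clearance`` is in mL/min (injected MBq over AUC in MBq·min/mL);
    ``auc_0_inf`` is in kBq·min/mL to match the concentration units.
    """

    lambda_tail: float  # 1/min
    half_life: float  # minutes; inf if no elimination detected
    auc_0_inf: float | None = None  # kBq·min/mL
    clearance: float | None = None  # mL/min
    analyte: Literal["total", "parent"] = "total"
    extrapolated_fraction: float | None = None
    flags: list[str] = field(default_factory=list)


def fit_monoexp_tail(
    curve: TimeActivityCurve, tail_start: float = 60.0,
    analyte: Literal["total", "parent"] = "total",
) -> PKParameters:
    """Log-linear least-squares fit of the terminal elimination phase.

    Uses samples at t ≥ ``tail_start`` with positive values (others are
    excluded); requires at least 3.  λ_tail ≤ 0 is flagged ("no elimination
    detected") with an infinite half-life sentinel.
    """
    if not curve.decay_corrected:
        raise ValueError("tail fitting expects a decay-corrected curve")
    mask = (curve.times >= tail_start) & (curve.values > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 positive samples at t >= {tail_start} min, got {int(mask.sum())}"
        )
    t, y = curve.times[mask], curve.values[mask]
    slope, _ = np.polyfit(t, np.log(y), 1)
    lam = -float(slope)
    if lam <= 0:
        return PKParameters(lam, math.inf, analyte=analyte,
                            flags=["no elimination detected"])
    return PKParameters(lam, math.log(2.0) / lam, analyte=analyte)


def _auc_linlog(t: np.ndarray, y: np.ndarray) -> float:
    """Linear-up/log-down trapezoid (exact on declining monoexponentials)."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        y0, y1 = y[i], y[i + 1]
        if y1 < y0 and y0 > 0 and y1 > 0:
            auc += dt * (y0 - y1) / math.log(y0 / y1)
        else:
            auc += dt * 0.5 * (y0 + y1)
    return auc


def clearance(
    curve: TimeActivityCurve,
    injected_activity_mbq: float,
    lambda_tail: float,
    method: Literal["linlog", "linear", "model"] = "linlog",
    back_extrapolate: bool = True,
    analyte: Literal["total", "parent"] = "total",
) -> PKParameters:
    """Non-compartmental clearance from a decay-corrected concentration curve.

    AUC₀→∞ combines the observed samples (linear-up/log-down trapezoid by
    default, plain trapezoid with ``method="linear"``), a log-linear
    back-extrapolation from the first two samples to t = 0 (default on),
    and the tail extrapolation C_last/λ_tail.  CL = injected activity/AUC;
    the extrapolated fraction is recorded and the result is flagged
    unreliable when it exceeds 50%.

    ``method="model"`` instead fits a nonnegative sum of exponentials to
    the whole curve and integrates it analytically (AUC = Σ A_i/λ_i);
    exact when the kinetics truly are a sum of exponentials, whereas the
    sample-based trapezoid carries a small discretisation error on sparse
    schedules.
    """
    if injected_activity_mbq <= 0:
        raise ValueError("injected activity must be > 0")
    if lambda_tail <= 0:
        raise ValueError("clearance requires a positive terminal rate")
    if not curve.decay_corrected:
        raise ValueError("clearance expects a decay-corrected curve")
    t, y = curve.times, curve.values

    if method == "model":
        from .kinetics import fit_sum_of_exponentials

        model = fit_sum_of_exponentials(curve, max_terms=3)
        if any(lam <= 0 and a > 0 for a, lam in model.terms):
            raise ValueError("fitted model has a non-decaying term: AUC diverges")
        auc = sum(a / lam for a, lam in model.terms if lam > 0)
        beyond = sum(a / lam * math.exp(-lam * t[-1]) for a, lam in model.terms if lam > 0)
        pre, tail = 0.0, beyond
    else:
        observed = _auc_linlog(t, y) if method == "linlog" else float(np.trapezoid(y, t))
        pre = 0.0
        if back_extrapolate and t[0] > 0:
            if y[0] > 0 and y[1] > 0 and y[1] < y[0]:
                lam0 = math.log(y[0] / y[1]) / (t[1] - t[0])
                c0 = y[0] * math.exp(lam0 * t[0])
                pre = (c0 - y[0]) / lam0 if method == "linlog" else t[0] * 0.5 * (c0 + y[0])
            else:
                pre = t[0] * y[0]
        tail = y[-1] / lambda_tail
        auc = observed + pre + tail  # kBq·min/mL

    extrap = (pre + tail) / auc if auc > 0 else math.nan
    flags = []
    if extrap > 0.5:
        flags.append("extrapolated AUC fraction > 50%: unreliable")
    cl = injected_activity_mbq * 1000.0 / auc  # MBq -> kBq so CL is mL/min
    return PKParameters(
        lambda_tail, math.log(2.0) / lambda_tail, auc_0_inf=float(auc),
        clearance=float(cl), analyte=analyte,
        extrapolated_fraction=float(extrap), flags=flags,
    )
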