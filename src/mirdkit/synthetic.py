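"""Synthetic whole-body kinetics simulator with known ground truth.

Generates complete synthetic subjects — per-organ time–activity curves,
bladder filling, venous blood/plasma samples, parent fractions and urine
voids — from a closed-form generating model, so every pipeline stage can
be tested against analytic truth without any downloads.

The generating model (decay-corrected, FIA):

* the body excretes a fraction ``f_u`` of the injected activity renally at
  rate ``λ_u``; body retention is R(t) = (1 − f_u) + f_u·e^{−λ_u t};
* each source organ washes out as a nonnegative sum of exponentials that
  stays inside R(t); the remainder of body is R(t) minus the organs;
* the bladder content is everything excreted minus everything voided;
* plasma is a biexponential; whole blood is plasma divided by a constant
  partition ratio; the parent fraction follows an exponential-plus-plateau
  curve; protein binding drifts linearly upward during the session.

Mass balance (organs + remainder + bladder + voided = 1) holds exactly by
construction before noise; noise is multiplicative lognormal applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .blood_pk import ParentFractionCurve, PlasmaSampleSeries
from .dosimetry import REMAINDER_KEY, SValueTable
from .kinetics import TimeActivityCurve, compute_suv
from .nuclide import GA68, Nuclide

__all__ = [
    "SubjectConfig",
    "GroundTruth",
    "SyntheticSubject",
    "generate_subject",
    "generate_outlier_subject",
    "generate_toy_svalue_table",
    "DEFAULT_ORGAN_KINETICS",
]

_LN2 = math.log(2.0)

#: Default per-organ washout terms (FIA amplitude, biologic rate 1/min).
#: Invented calibration reproducing the qualitative pattern of a renally
#: cleared small peptide: early blood-pool/heart/liver/kidney prominence,
#: later kidney/bladder dominance, small long-lived bone retention.
DEFAULT_ORGAN_KINETICS: dict[str, tuple[tuple[float, float], ...]] = {
    "kidneys": ((0.060, _LN2 / 20.0), (0.015, _LN2 / 400.0)),
    "liver": ((0.050, _LN2 / 25.0), (0.012, _LN2 / 500.0)),
    "heart contents": ((0.040, _LN2 / 8.0), (0.003, _LN2 / 200.0)),
    "lungs": ((0.025, _LN2 / 10.0), (0.005, _LN2 / 300.0)),
    "bone cortical": ((0.020, _LN2 / 60.0), (0.010, _LN2 / 2000.0)),
    "bone trabecular": ((0.004, _LN2 / 60.0), (0.0015, _LN2 / 2000.0)),
    "brain": ((0.005, _LN2 / 100.0), (0.001, _LN2 / 1000.0)),
    "pancreas": ((0.002, _LN2 / 50.0), (0.0004, _LN2 / 500.0)),
    "red marrow": ((0.010, _LN2 / 80.0), (0.003, _LN2 / 800.0)),
    "salivary glands": ((0.0006, _LN2 / 60.0), (0.0001, _LN2 / 600.0)),
    "spleen": ((0.004, _LN2 / 60.0), (0.001, _LN2 / 600.0)),
}

# Parent-fraction parameters anchored to 0.792 at 1 min and 0.043 at
# 10 min with a 0.02 long-lived plateau.
_PF_PLATEAU = 0.02
_PF_RATE = math.log((0.792 - _PF_PLATEAU) / (0.043 - _PF_PLATEAU)) / 9.0
_PF_AMPLITUDE = (0.792 - _PF_PLATEAU) * math.exp(_PF_RATE)


@dataclass(frozen=True)
class SubjectConfig:
    """Generating parameters of one synthetic subject.

    Defaults reproduce the healthy-cohort study conditions: 80 kg, 162 MBq
    injected, the 6-scan whole-body PET schedule and 13-point venous
    schedule, biologic excretion half-life 191 min, plasma:blood partition
    1.7, parent fraction 79%→4% between 1 and 10 min, protein binding
    drifting from ~13% to ~43%.
    """

    body_weight_kg: float = 80.0
    injected_activity_mbq: float = 162.0
    nuclide: Nuclide = GA68
    organ_kinetics: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_KINETICS)
    )
    excreted_fraction: float = 0.85
    excretion_half_life_min: float = 191.0
    void_times_min: tuple[float, ...] = ()  # subjects imaged continuously
    bladder_residual_volume_ml: float = 50.0
    urine_production_ml_per_min: float = 1.25
    plasma_partition: float = 1.7
    plasma_terms: tuple[tuple[float, float], ...] = (  # kBq/mL, 1/min
        (12.0, _LN2 / 4.0),
        (4.0, _LN2 / 106.9),
    )
    parent_amplitude: float = _PF_AMPLITUDE
    parent_rate: float = _PF_RATE
    parent_plateau: float = _PF_PLATEAU
    protein_bound_start_pct: float = 13.3
    protein_bound_end_pct: float = 42.7
    noise_sigma_pet: float = 0.03  # at a 60 s frame; scales as (frame/60)^-1/2
    noise_sigma_blood: float = 0.03
    scan_times_min: tuple[float, ...] = (1.0, 10.0, 20.0, 40.0, 100.0, 200.0)
    frame_durations_s: tuple[float, ...] = (30.0, 60.0, 120.0, 180.0, 300.0, 360.0)
    blood_times_min: tuple[float, ...] = (2, 3, 5, 6, 7, 10, 15, 20, 30, 60, 90, 180, 240)
    seed: int = 0

    @property
    def excretion_rate(self) -> float:
        return _LN2 / self.excretion_half_life_min

    def body_retention(self, t: np.ndarray) -> np.ndarray:
        f = self.excreted_fraction
        return (1.0 - f) + f * np.exp(-self.excretion_rate * np.asarray(t, float))

    def organ_fia(self, organ: str, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, lam in self.organ_kinetics[organ]:
            out = out + a * np.exp(-lam * t)
        return out

    def remainder_fia(self, t: np.ndarray) -> np.ndarray:
        total = sum(self.organ_fia(o, t) for o in self.organ_kinetics)
        return self.body_retention(t) - total

    def excreted_cumulative(self, t: np.ndarray) -> np.ndarray:
        f = self.excreted_fraction
        return f * (1.0 - np.exp(-self.excretion_rate * np.asarray(t, float)))

    def validate(self) -> None:
        uptake0 = sum(a for terms in self.organ_kinetics.values() for a, _ in terms)
        if uptake0 + 0.0 > 1.0:
            raise ValueError(f"organ uptake fractions sum to {uptake0:.3f} > 1")
        for organ, terms in self.organ_kinetics.items():
            if any(lam < 0 or a < 0 for a, lam in terms):
                raise ValueError(f"{organ}: negative amplitude or rate")
        if not 0.0 <= self.excreted_fraction <= 1.0:
            raise ValueError("excreted_fraction must be in [0, 1]")
        grid = np.linspace(0.0, 2000.0, 2001)
        if np.any(self.remainder_fia(grid) < -1e-12):
            raise ValueError("organ kinetics exceed body retention: remainder negative")
        if any(tv <= 0 for tv in self.void_times_min) or list(self.void_times_min) != sorted(
            set(self.void_times_min)
        ):
            raise ValueError("void times must be positive, sorted and unique")


@dataclass
class GroundTruth:
    """Closed-form truths of the generating model for recovery testing."""

    organ_tiacs_h: dict[str, float]  # incl. "urinary bladder" and remainder
    half_life_total_min: float
    cl_total_ml_min: float
    cl_parent_ml_min: float
    auc_total_kbq_min_ml: float
    auc_parent_kbq_min_ml: float
    partition_ratio: float
    parent_amplitude: float
    parent_rate: float
    parent_plateau: float


@dataclass
class SyntheticSubject:
    """One generated subject: sampled data plus the generating truth."""

    config: SubjectConfig
    tacs: dict[str, TimeActivityCurve]  # FIA, decay-corrected, incl. bladder/remainder
    bladder_concentration: TimeActivityCurve  # kBq/mL, decay-corrected
    plasma: PlasmaSampleSeries
    voids: pd.DataFrame
    ground_truth: GroundTruth

    @property
    def peak_bladder_suv(self) -> float:
        suvs = compute_suv(
            self.bladder_concentration.values,
            self.config.injected_activity_mbq,
            self.config.body_weight_kg,
        )
        return float(np.max(suvs))

    def mass_balance_residual(self, t: np.ndarray) -> np.ndarray:
        """organs + remainder + bladder + voided − 1 of the noise-free model."""
        cfg = self.config
        t = np.asarray(t, dtype=float)
        organs = sum(cfg.organ_fia(o, t) for o in cfg.organ_kinetics)
        remainder = cfg.remainder_fia(t)
        bladder, voided = _bladder_and_voided(cfg, t)
        return organs + remainder + bladder + voided - 1.0


def _bladder_and_voided(cfg: SubjectConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decay-corrected bladder content and cumulative voided FIA at times t."""
    t = np.asarray(t, dtype=float)
    excreted = cfg.excreted_cumulative(t)
    voided = np.zeros_like(t)
    for tv in cfg.void_times_min:
        amount = float(cfg.excreted_cumulative(np.asarray(tv))) - (
            float(cfg.excreted_cumulative(np.asarray(prev)))
            if (prev := _prev_void(cfg, tv)) is not None
            else 0.0
        )
        voided = voided + np.where(t >= tv, amount, 0.0)
    return excreted - voided, voided


def _prev_void(cfg: SubjectConfig, tv: float) -> float | None:
    earlier = [v for v in cfg.void_times_min if v < tv]
    return max(earlier) if earlier else None


def _bladder_tiac_truth(cfg: SubjectConfig, nuclide: Nuclide) -> float:
    """Closed-form TIAC of the generated bladder content, hours."""
    lam_u, lam_p, f = cfg.excretion_rate, nuclide.decay_constant, cfg.excreted_fraction

    def cycle(t0: float, t1: float) -> float:
        # integral of f (e^{-lam_u t0} - e^{-lam_u t}) e^{-lam_p t} over [t0, t1]
        e0, e1 = math.exp(-lam_p * t0), (math.exp(-lam_p * t1) if math.isfinite(t1) else 0.0)
        g0 = math.exp(-(lam_u + lam_p) * t0)
        g1 = math.exp(-(lam_u + lam_p) * t1) if math.isfinite(t1) else 0.0
        return f * (math.exp(-lam_u * t0) * (e0 - e1) / lam_p - (g0 - g1) / (lam_u + lam_p))

    bounds = [0.0, *cfg.void_times_min, math.inf]
    return sum(cycle(a, b) for a, b in zip(bounds[:-1], bounds[1:])) / 60.0


def _ground_truth(cfg: SubjectConfig) -> GroundTruth:
    lam_p = cfg.nuclide.decay_constant
    tiacs: dict[str, float] = {}
    for organ, terms in cfg.organ_kinetics.items():
        tiacs[organ] = sum(a / (lam + lam_p) for a, lam in terms) / 60.0
    f, lam_u = cfg.excreted_fraction, cfg.excretion_rate
    body = ((1.0 - f) / lam_p + f / (lam_u + lam_p)) / 60.0
    tiacs[REMAINDER_KEY] = body - sum(tiacs.values())
    tiacs["urinary bladder"] = _bladder_tiac_truth(cfg, cfg.nuclide)

    terms = cfg.plasma_terms
    auc_total = sum(a / lam for a, lam in terms)
    pf = ParentFractionCurve(cfg.parent_amplitude, cfg.parent_rate, cfg.parent_plateau)
    auc_parent, _ = quad(
        lambda t: sum(a * math.exp(-lam * t) for a, lam in terms) * pf(t),
        0.0, math.inf, limit=500,
    )
    d_kbq = cfg.injected_activity_mbq * 1000.0
    lam_tail = min(lam for _, lam in terms)
    return GroundTruth(
        organ_tiacs_h=tiacs,
        half_life_total_min=_LN2 / lam_tail,
        cl_total_ml_min=d_kbq / auc_total,
        cl_parent_ml_min=d_kbq / auc_parent,
        auc_total_kbq_min_ml=auc_total,
        auc_parent_kbq_min_ml=auc_parent,
        partition_ratio=cfg.plasma_partition,
        parent_amplitude=cfg.parent_amplitude,
        parent_rate=cfg.parent_rate,
        parent_plateau=cfg.parent_plateau,
    )


def _lognormal_factor(rng: np.random.Generator, sigma: np.ndarray | float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise factors."""
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
    z = rng.standard_normal(n)
    return np.exp(sigma * z - 0.5 * sigma**2)


def generate_subject(config: SubjectConfig | None = None) -> SyntheticSubject:
    """Generate one synthetic subject from the closed-form kinetic model.

    Mass balance holds exactly before noise; multiplicative lognormal noise
    (PET σ scaled by frame duration⁻¹ᐟ², γ-counter σ constant) is applied
    afterwards.  Identical config + seed gives byte-identical output.
    """
    cfg = config or SubjectConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t_scan = np.asarray(cfg.scan_times_min, dtype=float)
    frames = np.asarray(cfg.frame_durations_s, dtype=float)
    sigma_pet = cfg.noise_sigma_pet * np.sqrt(60.0 / frames)

    tacs: dict[str, TimeActivityCurve] = {}
    organ_order = [*cfg.organ_kinetics, REMAINDER_KEY, "urinary bladder"]
    bladder_fia, _ = _bladder_and_voided(cfg, t_scan)
    for organ in organ_order:
        if organ == REMAINDER_KEY:
            clean = cfg.remainder_fia(t_scan)
        elif organ == "urinary bladder":
            clean = bladder_fia
        else:
            clean = cfg.organ_fia(organ, t_scan)
        noisy = clean * _lognormal_factor(rng, sigma_pet, len(t_scan))
        tacs[organ] = TimeActivityCurve(
            organ, t_scan, noisy, units="FIA", decay_corrected=True,
            frame_durations=frames,
        )

    # bladder concentration: content / urine volume since last void
    volume = np.empty_like(t_scan)
    for i, t in enumerate(t_scan):
        prev = max([v for v in cfg.void_times_min if v <= t], default=0.0)
        volume[i] = cfg.bladder_residual_volume_ml + cfg.urine_production_ml_per_min * (t - prev)
    conc_clean = bladder_fia * cfg.injected_activity_mbq * 1000.0 / volume
    conc = conc_clean * _lognormal_factor(rng, sigma_pet, len(t_scan))
    bladder_conc = TimeActivityCurve(
        "urinary bladder", t_scan, conc, units="kBq/mL", decay_corrected=True,
        frame_durations=frames,
    )

    t_blood = np.asarray(cfg.blood_times_min, dtype=float)
    plasma_clean = np.zeros_like(t_blood)
    for a, lam in cfg.plasma_terms:
        plasma_clean = plasma_clean + a * np.exp(-lam * t_blood)
    pf_curve = ParentFractionCurve(cfg.parent_amplitude, cfg.parent_rate, cfg.parent_plateau)
    bound_pct = cfg.protein_bound_start_pct + (
        cfg.protein_bound_end_pct - cfg.protein_bound_start_pct
    ) * t_blood / t_blood[-1]
    sb = cfg.noise_sigma_blood
    plasma_vals = plasma_clean * _lognormal_factor(rng, sb, len(t_blood))
    blood_vals = (plasma_clean / cfg.plasma_partition) * _lognormal_factor(rng, sb, len(t_blood))
    sup_vals = (plasma_clean * (1.0 - bound_pct / 100.0)) * _lognormal_factor(rng, sb, len(t_blood))
    sup_vals = np.minimum(sup_vals, plasma_vals)  # assay consistency
    pf_vals = np.clip(pf_curve(t_blood) * _lognormal_factor(rng, sb, len(t_blood)), 0.0, 1.0)
    plasma = PlasmaSampleSeries(
        t_blood, blood_vals, plasma_vals, sup_vals, pf_vals, decay_corrected=True
    )

    rows = []
    for tv in cfg.void_times_min:
        prev = _prev_void(cfg, tv) or 0.0
        amount = float(cfg.excreted_cumulative(np.asarray(tv))) - float(
            cfg.excreted_cumulative(np.asarray(prev))
        )
        rows.append(
            {
                "time_min": tv,
                "voided_fia": amount,
                "urine_volume_ml": cfg.bladder_residual_volume_ml
                + cfg.urine_production_ml_per_min * (tv - prev),
            }
        )
    voids = pd.DataFrame(rows, columns=["time_min", "voided_fia", "urine_volume_ml"])

    return SyntheticSubject(cfg, tacs, bladder_conc, plasma, voids, _ground_truth(cfg))


def generate_outlier_subject(config: SubjectConfig | None = None) -> SyntheticSubject:
    """Dehydration-scenario subject: halved urine production, smaller residual.

    Only the urine-flow parameters change, so organ time–activity curves are
    unchanged (up to noise) while the bladder concentration — and hence its
    peak SUV — roughly doubles.
    """
    cfg = config or SubjectConfig()
    out = replace(
        cfg,
        urine_production_ml_per_min=cfg.urine_production_ml_per_min * 0.5,
        bladder_residual_volume_ml=cfg.bladder_residual_volume_ml * 0.6,
    )
    return generate_subject(out)


def generate_toy_svalue_table(
    n_organs: int, seed: int = 0, organ_names: Sequence[str] | None = None,
    whole_body_target: bool = False,
) -> SValueTable:
    """Small synthetic S-value table for tests and demos.

    Positive matrix with self-dose (diagonal) at least 10× any cross-dose,
    plus a remainder-of-body source row.  Deterministic per seed.  Entries
    are in mSv/(MBq·h); magnitudes are loosely representative of photon
    cross-fire in an adult phantom, not any published phantom.
    ``organ_names`` replaces the generic labels; ``whole_body_target`` adds
    a whole-body target column (mean cross-dose) so the effective-dose
    whole-body substitution policy can resolve.
    """
    if n_organs < 2:
        raise ValueError("need at least 2 organs")
    if organ_names is not None and len(organ_names) != n_organs:
        raise ValueError("organ_names length must equal n_organs")
    rng = np.random.default_rng(seed)
    organs = list(organ_names) if organ_names else [f"organ_{i + 1:02d}" for i in range(n_organs)]
    cross = rng.uniform(0.001, 0.01, size=(n_organs, n_organs))
    np.fill_diagonal(cross, 0.0)
    diag = 10.0 * cross.max(axis=1) * rng.uniform(1.0, 2.0, size=n_organs)
    matrix = cross + np.diag(diag)
    remainder = rng.uniform(0.001, 0.01, size=(1, n_organs))
    df = pd.DataFrame(
        np.vstack([matrix, remainder]), index=[*organs, REMAINDER_KEY], columns=organs
    )
    if whole_body_target:
        df["whole body"] = df.mean(axis=1)
    return SValueTable(phantom_id=f"toy-phantom-n{n_organs}-seed{seed}", matrix=df)
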