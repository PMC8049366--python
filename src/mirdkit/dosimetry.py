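"""MIRD-style organ dose engine and ICRP-103 effective dose.

Organ dose-equivalents follow the MIRD schema
``D(target) = Σ_source τ(source) · S(target ← source)`` with residence
times τ in hours and S-values in mSv/(MBq·h), giving doses in μSv/MBq.
For a pure positron/photon emitter the radiation weighting factor is 1,
so absorbed dose (μGy/MBq) and equivalent dose (μSv/MBq) coincide.

The effective dose applies the ICRP publication 103 tissue weighting
factors to the organ dose-equivalents, with the conventional mappings
(gonads ← testes for a male phantom, bone surface ← osteogenic cells,
colon ← mean of left and right colon) and a substitution policy for
weighted tissues absent from the dose report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .kinetics import ResidenceTimeSet

__all__ = [
    "SValueTable",
    "TissueWeights",
    "DoseReport",
    "ICRP103_WEIGHTS",
    "compute_absorbed_doses",
    "effective_dose",
    "dose_for_administration",
]

REMAINDER_KEY = "remainder of body"


def _norm(name: str) -> str:
    """Canonicalise an organ name for matching: lowercase, alphanumeric words."""
    return " ".join(re.findall(r"[a-z0-9]+", name.lower()))


@dataclass
class SValueTable:
    """Source → target dose-factor matrix for one reference phantom.

    ``matrix`` is a DataFrame with source organs as the index and target
    organs as columns, entries in mSv/(MBq·h).  A designated
    remainder-of-body source row is required so every
    :class:`ResidenceTimeSet` can be resolved.
    """

    phantom_id: str
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ValueError("S-value table contains negative entries")

    @property
    def sources(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def targets(self) -> list[str]:
        return list(self.matrix.columns)

    def resolve_source(self, name: str) -> str:
        lookup = {_norm(s): s for s in self.matrix.index}
        key = _norm(name)
        if key not in lookup:
            raise KeyError(
                f"source organ {name!r} not in S-value table; "
                f"candidates: {sorted(lookup.values())}"
            )
        return lookup[key]


# ICRP publication 103 tissue weighting factors (sum = 1).
ICRP103_REMAINDER_TISSUES = [
    "adrenals",
    "extrathoracic region",
    "gallbladder",
    "heart",
    "kidneys",
    "lymphatic nodes",
    "muscle",
    "oral mucosa",
    "pancreas",
    "prostate",
    "small intestine",
    "spleen",
    "thymus",
]

_ICRP103_W = {
    "red marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "gonads": 0.08,
    "urinary bladder": 0.04,
    "esophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone surface": 0.01,
    "brain": 0.01,
    "salivary glands": 0.01,
    "skin": 0.01,
    "remainder": 0.12,
}


@dataclass
class TissueWeights:
    """Tissue weighting factors w_T with an optional remainder-tissue list.

    The remainder weight (if a ``"remainder"`` key is present) is applied
    to the arithmetic mean of the ``remainder_tissues`` doses.
    """

    weights: dict[str, float]
    remainder_tissues: list[str] = field(default_factory=list)
    name: str = "custom"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("tissue weights must be nonnegative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"tissue weights must sum to 1 exactly, got {total!r}")


#: The ICRP-103 weights with the male remainder tissue list.
ICRP103_WEIGHTS = TissueWeights(
    dict(_ICRP103_W), list(ICRP103_REMAINDER_TISSUES), name="ICRP-103"
)

# Weighted-tissue -> dose-report organ-name candidates (normalised).
_TISSUE_ALIASES: dict[str, list[str]] = {
    "red marrow": ["red marrow", "bone marrow"],
    "lung": ["lungs", "lung"],
    "stomach": ["stomach wall", "stomach"],
    "breast": ["breast", "breasts"],
    "gonads": ["gonads", "testes", "ovaries"],
    "urinary bladder": ["urinary bladder wall", "urinary bladder", "bladder wall", "bladder"],
    "esophagus": ["esophagus", "oesophagus"],
    "liver": ["liver"],
    "thyroid": ["thyroid"],
    "bone surface": ["bone surface", "osteogenic cells", "bone surfaces"],
    "brain": ["brain"],
    "salivary glands": ["salivary glands", "salivary gland"],
    "skin": ["skin"],
    "adrenals": ["adrenals", "adrenal glands"],
    "extrathoracic region": ["extrathoracic region", "extrathoracic airways", "et region"],
    "gallbladder": ["gallbladder wall", "gallbladder", "gall bladder wall", "gall bladder"],
    "heart": ["heart wall", "heart"],
    "kidneys": ["kidneys", "kidney"],
    "lymphatic nodes": ["lymphatic nodes", "lymph nodes"],
    "muscle": ["muscle"],
    "oral mucosa": ["oral mucosa"],
    "pancreas": ["pancreas"],
    "prostate": ["prostate"],
    "small intestine": ["small intestine", "small intestine wall"],
    "spleen": ["spleen"],
    "thymus": ["thymus"],
}
_COLON_LEFT = ["colon left", "left colon"]
_COLON_RIGHT = ["colon right", "right colon"]


@dataclass
class DoseReport:
    """Per-target organ dose-equivalents (μSv/MBq) and effective dose (mSv/MBq)."""

    organ_doses: dict[str, float]  # μSv/MBq
    effective_dose_msv_per_mbq: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.organ_doses.items() if v < 0}
        if bad:
            raise ValueError(f"negative organ doses: {bad}")

    def dose(self, organ: str) -> float:
        key = _norm(organ)
        for name, d in self.organ_doses.items():
            if _norm(name) == key:
                return d
        raise KeyError(organ)

    def check_effective_dose_bounds(self) -> None:
        """E (in μSv/MBq) must lie within [min, max] organ dose when w_T sum to 1."""
        if self.effective_dose_msv_per_mbq is None:
            return
        e = self.effective_dose_msv_per_mbq * 1000.0
        lo, hi = min(self.organ_doses.values()), max(self.organ_doses.values())
        if not (lo - 1e-9 <= e <= hi + 1e-9):
            raise ValueError(
                f"effective dose {e:.3f} μSv/MBq outside organ dose range [{lo}, {hi}]"
            )


def compute_absorbed_doses(tiacs: ResidenceTimeSet, svalues: SValueTable) -> DoseReport:
    """Organ dose-equivalents from residence times and an S-value table.

    D(target) = Σ_source τ(source)·S(target←source); τ in hours, S in
    mSv/(MBq·h) → doses in μSv/MBq.  Linear in the residence times.
    """
    tau = tiacs.as_mapping(include_remainder=True)
    rows = [svalues.resolve_source(organ) for organ in tau]
    vec = np.array([tau[o] for o in tau], dtype=float)
    sub = svalues.matrix.loc[rows].values  # (n_sources, n_targets)
    doses_msv = vec @ sub
    organ_doses = {t: float(d) * 1000.0 for t, d in zip(svalues.targets, doses_msv)}
    return DoseReport(
        organ_doses,
        provenance={
            "phantom": svalues.phantom_id,
            "residence_time_sources": sorted(tau),
        },
    )


def _lookup(doses_by_norm: Mapping[str, float], candidates: list[str]) -> float | None:
    for c in candidates:
        if c in doses_by_norm:
            return doses_by_norm[c]
    return None


def effective_dose(
    report: DoseReport,
    weights: TissueWeights | None = None,
    substitution: Literal["whole_body", "omit_renormalize"] | None = "whole_body",
    whole_body_organ: str = "whole body",
) -> float:
    """ICRP-style effective dose E = Σ_T w_T·H_T, in mSv/MBq.

    Tissue doses are resolved from the report with the conventional
    mappings (colon = mean of left and right colon, gonads = testes for a
    male phantom, bone surface = osteogenic cells); the remainder weight
    applies to the arithmetic mean of the remainder tissues.  Weighted
    tissues missing from the report are filled per ``substitution``:

    - ``"whole_body"`` (default): use the report's whole-body dose;
    - ``"omit_renormalize"``: drop missing tissues and renormalise weights;
    - ``None``: raise on any missing tissue.

    The result is also stored on ``report.effective_dose_msv_per_mbq``.
    """
    w = weights or ICRP103_WEIGHTS
    doses = {_norm(k): v for k, v in report.organ_doses.items()}
    wb = _lookup(doses, [_norm(whole_body_organ), "whole body", "total body"])

    def tissue_dose(tissue: str) -> float | None:
        key = _norm(tissue)
        if key == "colon":
            left, right = _lookup(doses, _COLON_LEFT), _lookup(doses, _COLON_RIGHT)
            if left is not None and right is not None:
                return 0.5 * (left + right)
            return _lookup(doses, ["colon"])
        direct = _lookup(doses, _TISSUE_ALIASES.get(key, [key]))
        return direct

    def resolve(tissue: str) -> float | None:
        d = tissue_dose(tissue)
        if d is not None:
            return d
        if substitution == "whole_body":
            if wb is None:
                raise ValueError(
                    f"tissue {tissue!r} missing and no whole-body dose available "
                    "for substitution"
                )
            return wb
        if substitution == "omit_renormalize":
            return None
        raise ValueError(f"tissue {tissue!r} missing from dose report and no policy set")

    contributions: list[tuple[float, float]] = []  # (w_T, H_T)
    for tissue, w_t in w.weights.items():
        if tissue == "remainder":
            rem = [resolve(t) for t in w.remainder_tissues]
            rem_present = [d for d in rem if d is not None]
            if not rem_present:
                raise ValueError("no remainder tissues resolvable")
            contributions.append((w_t, float(np.mean(rem_present))))
        else:
            d = resolve(tissue)
            if d is None:
                continue  # omit_renormalize
            contributions.append((w_t, d))

    w_total = sum(wt for wt, _ in contributions)
    e_usv = sum(wt * d for wt, d in contributions) / w_total
    e_msv = e_usv / 1000.0
    report.effective_dose_msv_per_mbq = e_msv
    report.provenance["weights"] = w.name
    report.provenance["substitution"] = substitution
    return e_msv


def dose_for_administration(
    effective_dose_coeff_msv_per_mbq: float, administered_activity_mbq: float
) -> float:
    """Effective dose (mSv) for an administered activity (MBq).

    Full precision is returned; human-readable reports round to
    2 significant figures.
    """
    if effective_dose_coeff_msv_per_mbq < 0 or administered_activity_mbq < 0:
        raise ValueError("dose coefficient and administered activity must be >= 0")
    return effective_dose_coeff_msv_per_mbq * administered_activity_mbq


def format_dose_2sf(dose_msv: float) -> str:
    """Format a dose to 2 significant figures, e.g. 3.3 mSv from 150 MBq."""
    if dose_msv == 0:
        return "0.0"
    return f"{float(f'{dose_msv:.2g}'):g}"
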