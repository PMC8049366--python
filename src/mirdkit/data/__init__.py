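"""Bundled reference data.

Published cohort summary statistics from the first-in-humans dosimetry of
the ⁶⁸Ga-DOTA-Siglec-9 inflammation tracer (six healthy adult men,
162 ± 4 MBq injected): per-source-organ residence times (normalized number
of disintegrations, hours) and per-target-organ dose-equivalent estimates
(μSv/MBq) on an adult male ~70 kg reference phantom, with the ICRP-103
effective dose coefficient.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..dosimetry import DoseReport
from ..kinetics import ResidenceTimeSet

__all__ = [
    "load_reference_residence_times",
    "load_reference_dose_table",
    "reference_residence_time_set",
    "reference_dose_report",
    "REFERENCE_EFFECTIVE_DOSE",
    "REFERENCE_ADMINISTRATION",
]

#: Published effective dose coefficient, mSv/MBq (ICRP-103): mean ± SD and subject range.
REFERENCE_EFFECTIVE_DOSE = {"mean": 0.022, "sd": 0.002, "min": 0.020, "max": 0.024}

#: Published worked example: 150 MBq administered at 0.022 mSv/MBq → 3.3 mSv.
REFERENCE_ADMINISTRATION = {"coefficient_msv_per_mbq": 0.022, "activity_mbq": 150.0, "dose_msv": 3.3}


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_residence_times() -> pd.DataFrame:
    """Cohort residence-time summary (mean/SD/min/max, hours) per source organ."""
    return _load("cohort_residence_times.csv")


def load_reference_dose_table() -> pd.DataFrame:
    """Cohort dose-equivalent summary (mean/SD/min/max, μSv/MBq) per target organ."""
    return _load("cohort_dose_equivalents.csv")


def reference_residence_time_set(column: str = "mean_h") -> ResidenceTimeSet:
    """The cohort residence times as a :class:`ResidenceTimeSet`."""
    df = load_reference_residence_times()
    organs, remainder = {}, 0.0
    for _, row in df.iterrows():
        if row["site"].strip().lower() == "remainder of body":
            remainder = float(row[column])
        else:
            organs[row["site"]] = float(row[column])
    return ResidenceTimeSet(organs, remainder)


def reference_dose_report(column: str = "mean_usv_per_mbq") -> DoseReport:
    """The cohort per-organ dose-equivalents as a :class:`DoseReport`."""
    df = load_reference_dose_table()
    return DoseReport(
        {row["site"]: float(row[column]) for _, row in df.iterrows()},
        provenance={"source": "published cohort summary", "column": column},
    )
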