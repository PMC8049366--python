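"""CSV/JSON readers and writers for all pipeline formats.

Formats
-------
TAC CSV
    ``organ,time_min,value,units,decay_corrected`` — one row per sample,
    multiple organs per file, UTF-8, ``.`` decimal separator.
Plasma CSV
    ``time_min,whole_blood,plasma,supernatant,parent_fraction`` — blank
    cells allowed in the optional columns.
S-value CSV
    first column ``source``, remaining columns target organ names, cells
    in mSv/(MBq·h); phantom metadata in a JSON sidecar.
Dose report / PK report / fitted models
    JSON at full precision; human-readable text tables round to 4 d.p.
    (residence times, hours), 1 d.p. (organ doses, μSv/MBq) and 3 d.p.
    (effective dose, mSv/MBq).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blood_pk import PKParameters, PlasmaSampleSeries
from .dosimetry import DoseReport, SValueTable
from .kinetics import ExponentialModel, ResidenceTimeSet, TimeActivityCurve

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_svalue_csv",
    "write_svalue_csv",
    "write_fitted_models_json",
    "read_fitted_models_json",
    "write_dose_report_json",
    "read_dose_report_json",
    "format_dose_report_text",
    "write_pk_report_json",
    "write_residence_times_csv",
    "read_residence_times_csv",
]

_TAC_COLUMNS = ["organ", "time_min", "value", "units", "decay_corrected"]
_PLASMA_COLUMNS = ["time_min", "whole_blood", "plasma", "supernatant", "parent_fraction"]


def _check_header(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring unknown column(s) {extra}")


def _parse_numeric(df: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    # exact strtod via Python float(); pandas' fast parser loses ulps
    out = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df[column].tolist()):
        text = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
        if text == "":
            out[i] = np.nan
            continue
        try:
            out[i] = float(text)
        except ValueError:
            raise ValueError(
                f"{path}: malformed value in column {column!r} at line {i + 2}"
            ) from None
    return out


def read_tac_csv(path: str | Path) -> dict[str, TimeActivityCurve]:
    """Read a multi-organ TAC CSV into a dict of curves (organ order preserved)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_header(df, _TAC_COLUMNS, path)
    times = _parse_numeric(df, "time_min", path)
    values = _parse_numeric(df, "value", path)
    out: dict[str, TimeActivityCurve] = {}
    for organ in df["organ"].unique():
        mask = (df["organ"] == organ).to_numpy()
        units = df.loc[mask, "units"].iloc[0]
        dc = str(df.loc[mask, "decay_corrected"].iloc[0]).strip().lower() in ("true", "1", "yes")
        out[organ] = TimeActivityCurve(
            organ, times[mask], values[mask], units=units, decay_corrected=dc
        )
    return out


def write_tac_csv(tacs: dict[str, TimeActivityCurve], path: str | Path) -> None:
    rows = []
    for organ, curve in tacs.items():
        for t, v in zip(curve.times, curve.values):
            rows.append(
                {
                    "organ": organ,
                    "time_min": repr(float(t)),
                    "value": repr(float(v)),
                    "units": curve.units,
                    "decay_corrected": str(curve.decay_corrected).lower(),
                }
            )
    pd.DataFrame(rows, columns=_TAC_COLUMNS).to_csv(path, index=False)


def read_plasma_csv(path: str | Path) -> PlasmaSampleSeries:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_header(df, _PLASMA_COLUMNS, path)
    sup = _parse_numeric(df, "supernatant", path)
    pf = _parse_numeric(df, "parent_fraction", path)
    return PlasmaSampleSeries(
        _parse_numeric(df, "time_min", path),
        _parse_numeric(df, "whole_blood", path),
        _parse_numeric(df, "plasma", path),
        protein_free_supernatant=None if np.all(np.isnan(sup)) else sup,
        parent_fraction=None if np.all(np.isnan(pf)) else pf,
    )


def write_plasma_csv(series: PlasmaSampleSeries, path: str | Path) -> None:
    def col(arr: np.ndarray | None) -> list[str]:
        if arr is None:
            return [""] * len(series.times)
        return ["" if np.isnan(v) else repr(float(v)) for v in arr]

    df = pd.DataFrame(
        {
            "time_min": [repr(float(t)) for t in series.times],
            "whole_blood": col(series.whole_blood),
            "plasma": col(series.plasma),
            "supernatant": col(series.protein_free_supernatant),
            "parent_fraction": col(series.parent_fraction),
        }
    )
    df.to_csv(path, index=False)


def read_svalue_csv(path: str | Path, sidecar: str | Path | None = None) -> SValueTable:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "source":
        raise ValueError(f"{path}: first column must be 'source'")
    matrix = df.set_index("source").astype(float)
    matrix.index.name = None
    phantom = "unspecified"
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if sidecar.exists():
        phantom = json.loads(sidecar.read_text()).get("phantom_id", phantom)
    return SValueTable(phantom_id=phantom, matrix=matrix)


def write_svalue_csv(table: SValueTable, path: str | Path) -> None:
    path = Path(path)
    table.matrix.rename_axis("source").to_csv(path)
    path.with_suffix(".json").write_text(
        json.dumps({"phantom_id": table.phantom_id}, indent=1) + "\n"
    )


def write_fitted_models_json(models: dict[str, ExponentialModel], path: str | Path) -> None:
    payload = {
        organ: {
            "terms": [{"A": a, "lambda_per_min": lam} for a, lam in m.terms],
            "domain_decay_corrected": m.domain_decay_corrected,
            "units": m.units,
            "rss": m.rss,
            "n_samples": m.n_samples,
        }
        for organ, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_fitted_models_json(path: str | Path) -> dict[str, ExponentialModel]:
    payload = json.loads(Path(path).read_text())
    return {
        organ: ExponentialModel(
            [(t["A"], t["lambda_per_min"]) for t in entry["terms"]],
            entry["domain_decay_corrected"],
            entry["units"],
            organ,
            entry.get("rss", float("nan")),
            entry.get("n_samples", 0),
        )
        for organ, entry in payload.items()
    }


def write_dose_report_json(report: DoseReport, path: str | Path) -> None:
    payload = {
        "organ_dose_equivalents_usv_per_mbq": report.organ_doses,
        "effective_dose_msv_per_mbq": report.effective_dose_msv_per_mbq,
        "provenance": report.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_dose_report_json(path: str | Path) -> DoseReport:
    payload = json.loads(Path(path).read_text())
    return DoseReport(
        payload["organ_dose_equivalents_usv_per_mbq"],
        payload.get("effective_dose_msv_per_mbq"),
        payload.get("provenance", {}),
    )


def format_dose_report_text(report: DoseReport) -> str:
    """Formatted table: organ doses to 1 d.p. μSv/MBq, E to 3 d.p. mSv/MBq."""
    width = max(len(o) for o in report.organ_doses) + 2
    lines = [f"{'Site':<{width}}Dose equivalent (uSv/MBq)"]
    for organ, dose in report.organ_doses.items():
        lines.append(f"{organ:<{width}}{dose:.1f}")
    if report.effective_dose_msv_per_mbq is not None:
        lines.append(
            f"{'Effective dose':<{width}}{report.effective_dose_msv_per_mbq:.3f} mSv/MBq"
        )
    return "\n".join(lines) + "\n"


def write_pk_report_json(params: dict[str, PKParameters], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: dataclasses.asdict(p) for k, p in params.items()}, indent=1, default=float)
        + "\n"
    )


def write_residence_times_csv(tiacs: ResidenceTimeSet, path: str | Path) -> None:
    rows = [{"source": o, "tiac_h": repr(float(v))} for o, v in tiacs.organs.items()]
    rows.append({"source": "remainder of body", "tiac_h": repr(float(tiacs.remainder_of_body))})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_residence_times_csv(path: str | Path) -> ResidenceTimeSet:
    df = pd.read_csv(path)
    organs, remainder = {}, 0.0
    for _, row in df.iterrows():
        if str(row["source"]).strip().lower() == "remainder of body":
            remainder = float(row["tiac_h"])
        else:
            organs[str(row["source"])] = float(row["tiac_h"])
    return ResidenceTimeSet(organs, remainder)
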