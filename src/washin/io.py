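"""CSV/YAML input-output for records, parameters and calibration data.

The only tabular dialect is comma-separated UTF-8 with '.' decimals.
Output files embed the generating command, seed and package version as
``#`` comment lines, and loaders skip such lines.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import VaporizerMeasurement
from .fitting import WashInRecord
from .params import PRINTED_PARAMS, DeliverySettings, PatientCovariates, \
    WashInModelParams

__all__ = [
    "RECORD_COLUMNS",
    "read_records",
    "write_records",
    "records_from_frame",
    "records_to_frame",
    "read_measurements",
    "write_measurements",
    "load_params",
    "save_params",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["patient_id", "height_cm", "weight_kg", "age_years",
                  "fgf", "dial", "time_s", "fa_pct"]
MEASUREMENT_COLUMNS = ["dial_pct", "fgf", "output_pct"]


def _comment_header(meta: Optional[Dict] = None) -> str:
    from . import __version__

    lines = [f"# washin v{__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def records_from_frame(df: pd.DataFrame) -> List[WashInRecord]:
    """Group a long-format records table into per-patient wash-in records."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if df.empty:
        raise ValueError("no records in input")
    records = []
    for pid, grp in df.groupby("patient_id", sort=True):
        for col in ("fgf", "dial", "height_cm", "weight_kg", "age_years"):
            if grp[col].nunique(dropna=False) > 1:
                raise ValueError(
                    f"non-constant settings for patient {pid!r}: column {col}")
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) == 0):
            raise ValueError(f"duplicate sample times for patient {pid!r}")
        row = grp.iloc[0]
        patient = PatientCovariates(
            height_cm=float(row["height_cm"]),
            weight_kg=None if pd.isna(row["weight_kg"]) else float(row["weight_kg"]),
            age_years=None if pd.isna(row["age_years"]) else float(row["age_years"]),
        )
        settings = DeliverySettings(fgf=float(row["fgf"]), dial=float(row["dial"]))
        records.append(WashInRecord(
            patient=patient, settings=settings, time_s=times,
            fa_pct=grp["fa_pct"].to_numpy(dtype=float), patient_id=str(pid)))
    return records


def records_to_frame(records: Sequence[WashInRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for t, fa in zip(rec.time_s, rec.fa_pct):
            rows.append({
                "patient_id": rec.patient_id,
                "height_cm": rec.patient.height_cm,
                "weight_kg": rec.patient.weight_kg,
                "age_years": rec.patient.age_years,
                "fgf": rec.settings.fgf,
                "dial": rec.settings.dial,
                "time_s": t,
                "fa_pct": fa,
            })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def read_records(path) -> List[WashInRecord]:
    """Read per-patient wash-in records from a long-format CSV."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"no records in {path}")
    return records_from_frame(df)


def write_records(records: Sequence[WashInRecord], path,
                  meta: Optional[Dict] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_header(meta))
        records_to_frame(records).to_csv(fh, index=False)


def read_measurements(path) -> List[VaporizerMeasurement]:
    """Read vaporizer calibration triples (dial_pct, fgf, output_pct)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if df.empty:
        raise ValueError(f"no measurements in {path}")
    return [VaporizerMeasurement(dial=float(r.dial_pct), fgf=float(r.fgf),
                                 output=float(r.output_pct))
            for r in df.itertuples()]


def write_measurements(measurements: Sequence[VaporizerMeasurement], path,
                       meta: Optional[Dict] = None) -> None:
    df = pd.DataFrame(
        [{"dial_pct": m.dial, "fgf": m.fgf, "output_pct": m.output}
         for m in measurements], columns=MEASUREMENT_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_header(meta))
        df.to_csv(fh, index=False)


def load_params(source: Union[str, "os.PathLike"]) -> WashInModelParams:
    """Load model coefficients.

    The literal token ``"printed"`` returns the published reference
    coefficients; otherwise ``source`` is a flat key-value YAML file
    validated against the parameter invariants.
    """
    if isinstance(source, str) and source == "printed":
        return PRINTED_PARAMS
    with open(source, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {source} is not a key-value mapping")
    data.pop("_meta", None)
    return WashInModelParams.from_dict(data)


def save_params(params: WashInModelParams, path,
                meta: Optional[Dict] = None) -> None:
    payload = params.to_dict()
    if meta:
        payload["_meta"] = dict(meta)
    from . import __version__

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# washin v{__version__} model coefficients\n")
        yaml.safe_dump(payload, fh, sort_keys=True)
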