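"""Patient-level trial records.

One row per patient: stage (1 or 2), standardized and raw doses, the binary
DLT outcome ``dlt`` and the binary efficacy outcome ``eff`` (NA while not
yet observed — efficacy needs three or more treatment cycles, so stage-1
responses only enter the likelihood from the first stage-2 analysis on).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

COLUMNS = ["patient_id", "stage", "x_std", "y_std", "x_raw", "y_raw", "dlt", "eff", "cohort"]


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    stage: int
    x_std: float
    y_std: float
    dlt: int
    eff: Optional[int] = None
    cohort: int = 0
    x_raw: Optional[float] = None
    y_raw: Optional[float] = None

    def __post_init__(self):
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.dlt not in (0, 1):
            raise ValueError("dlt must be 0 or 1")
        if self.eff is not None and self.eff not in (0, 1):
            raise ValueError("eff must be 0, 1 or None")


def to_frame(records) -> pd.DataFrame:
    """Build the canonical patient-record DataFrame from PatientRecord rows."""
    rows = [{
        "patient_id": r.patient_id, "stage": r.stage,
        "x_std": r.x_std, "y_std": r.y_std,
        "x_raw": r.x_raw, "y_raw": r.y_raw,
        "dlt": r.dlt, "eff": np.nan if r.eff is None else r.eff,
        "cohort": r.cohort,
    } for r in records]
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df


def empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=COLUMNS)


def validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("stage", "x_std", "y_std", "dlt") if c not in df.columns]
    if missing:
        raise ValueError(f"patient records missing required columns: {missing}")
    if len(df) and not df["stage"].isin([1, 2]).all():
        raise ValueError("stage must be 1 or 2")
    if len(df) and not df["dlt"].dropna().isin([0, 1]).all():
        raise ValueError("dlt must be binary")
    return df


def with_efficacy_observed(df: pd.DataFrame) -> pd.DataFrame:
    """Rows whose efficacy outcome has been observed."""
    return df[df["eff"].notna()]


def write_csv(df: pd.DataFrame, path) -> None:
    validate_frame(df).to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    return validate_frame(pd.read_csv(path))
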