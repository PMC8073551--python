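"""CSV reading/writing for the package's long-format tables.

All tables are plain CSV with fixed headers:

* ExpressionSeries: ``gene,condition,experiment,time_h,value``
* CqTable:          ``gene,condition,experiment,time_h,cq``
* efficiencies:     ``gene,efficiency``
* GrowthTable:      ``time_h,od600,cfu_per_ml``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError

EXPRESSION_COLUMNS = ["gene", "condition", "experiment", "time_h", "value"]
CQ_COLUMNS = ["gene", "condition", "experiment", "time_h", "cq"]
GROWTH_COLUMNS = ["time_h", "od600", "cfu_per_ml"]


def _read(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_expression(path) -> pd.DataFrame:
    return _read(path, EXPRESSION_COLUMNS, ["time_h", "value"])


def read_cq(path) -> pd.DataFrame:
    return _read(path, CQ_COLUMNS, ["time_h", "cq"])


def read_efficiencies(path) -> dict[str, float]:
    df = _read(path, ["gene", "efficiency"], ["efficiency"])
    return dict(zip(df["gene"], df["efficiency"]))


def read_growth(path) -> pd.DataFrame:
    return _read(path, GROWTH_COLUMNS, GROWTH_COLUMNS)


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
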