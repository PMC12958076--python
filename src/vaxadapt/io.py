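"""Occasion-level CSV dialect.

One row per scheduled vaccine occasion; all dates are integer day indices
from trial start (day 0); ``receipt_day`` is the signed offset from the due
date and is empty when no receipt was recorded. Round-trips bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .population import OCCASION_COLUMNS

_DTYPES = {
    "occasion_id": "int64",
    "parent_id": "int64",
    "child_id": "int64",
    "clinic_id": "int64",
    "schedule_point": "int64",
    "due_date": "int64",
    "receipt_day": "Int64",
    "arm_framing": "string",
    "arm_timing": "Int64",
    "epoch": "int64",
    "is_index": "boolean",
}


def write_occasions_csv(occasions: pd.DataFrame, path: Union[str, Path]) -> None:
    out = occasions.loc[:, OCCASION_COLUMNS].copy()
    for col, dt in _DTYPES.items():
        out[col] = out[col].astype(dt)
    out.to_csv(path, index=False)


def read_occasions_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=_DTYPES)
    return df.loc[:, OCCASION_COLUMNS]
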