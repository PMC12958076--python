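"""Printed summary counts from a completed adaptive SMS-reminder trial,
used as reporting fixtures and exact-arithmetic checks.

These are arm-level index-occasion counts (assignments, on-time
vaccinations, and on-time receipts binned by day relative to due) and the
early-vaccination exclusion totals. They are aggregate inputs, not
individual-level data; :func:`occasions_from_arm_counts` expands them into
a synthetic occasion table that reproduces the counts exactly for testing
the report generators.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

#: (timing, framing, index_n, ontime_n, bin(-14,0], bin(0,7], bin(7,28])
PUBLISHED_ARM_COUNTS: List[Tuple] = [
    (None, "control", 637, 286, 31, 118, 137),
    (-14, "neutral", 409, 168, 21, 73, 74),
    (-14, "positive", 893, 420, 63, 204, 153),
    (-14, "risk", 985, 438, 69, 202, 167),
    (-14, "social", 483, 209, 37, 95, 77),
    (0, "neutral", 380, 153, 16, 68, 69),
    (0, "positive", 560, 246, 36, 108, 102),
    (0, "risk", 905, 400, 61, 168, 171),
    (0, "social", 984, 468, 68, 198, 202),
    (7, "neutral", 898, 389, 59, 132, 198),
    (7, "positive", 878, 409, 59, 149, 201),
    (7, "risk", 811, 363, 43, 142, 178),
    (7, "social", 1110, 489, 73, 185, 231),
]

#: total scheduled occasions, early-vaccination exclusions, exclusions at 2 months
PUBLISHED_EXCLUSION_TOTALS = (22_865, 1_366, 1_310)


def published_arm_counts() -> pd.DataFrame:
    return pd.DataFrame(
        PUBLISHED_ARM_COUNTS,
        columns=["timing", "framing", "index_n", "ontime_n", "bin_early", "bin_week", "bin_late"],
    )


def occasions_from_arm_counts(counts: pd.DataFrame = None) -> pd.DataFrame:
    """Expand arm-level counts into a synthetic occasion-level table whose
    per-arm totals and receipt-day bins match the counts exactly.

    Receipt days are placed at representative points of each bin (-7, 4, 18),
    not-on-time occasions get no receipt record. Synthetic stand-in for the
    unavailable individual-level data; only totals are meaningful.
    """
    if counts is None:
        counts = published_arm_counts()
    rows = []
    pid = 0
    for r in counts.itertuples(index=False):
        framing = "control" if r.framing == "control" else r.framing
        timing = pd.NA if r.timing is None or pd.isna(r.timing) else int(r.timing)
        days = [-7] * r.bin_early + [4] * r.bin_week + [18] * r.bin_late
        days += [pd.NA] * (r.index_n - r.ontime_n)
        for d in days:
            rows.append((pid, pid, pid, 0, 12, 100, d, framing, timing, 3, True))
            pid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "occasion_id", "parent_id", "child_id", "clinic_id", "schedule_point",
            "due_date", "receipt_day", "arm_framing", "arm_timing", "epoch", "is_index",
        ],
    ).astype({"receipt_day": "Int64", "arm_timing": "Int64", "arm_framing": "string"})
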