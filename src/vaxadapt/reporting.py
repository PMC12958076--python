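"""Arm-level report tables from occasion data and posterior summaries.

``table_one`` tabulates index occasions per arm: assignments, on-time
vaccinations (proportion to 2 decimals) and receipt-day bins (-14,0],
(0,7], (7,28] whose counts partition the on-time total. ``table_two``
lays out the posterior odds-ratio grid (median, 95% CrI, Pr(>1)) across
the five model structures, with margin cells populated only by the reduced
models that define them. Underlying CSVs keep full precision; display
rounding follows the conventional printed style (proportions 2 dp,
percentages to integers, ORs 2 dp).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .arms import FRAMINGS, TIMINGS
from .schedule import (
    STATUS_EXCLUDED_EARLY,
    STATUS_ONTIME,
    classify_endpoints,
)

_TIMING_LABEL = {-14: "Day -14", 0: "Day 0", 7: "Day +7", None: "None"}


def _bin_receipts(receipts: pd.Series) -> Tuple[int, int, int]:
    r = receipts.astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    b1 = int(((r >= -14) & (r <= 0)).sum())
    b2 = int(((r > 0) & (r <= 7)).sum())
    b3 = int(((r > 7) & (r <= 28)).sum())
    return b1, b2, b3


def table_one(occasions: pd.DataFrame) -> pd.DataFrame:
    """Index-occasion report: one row per arm (control first) plus a totals row."""
    occ = occasions[occasions["is_index"].astype(bool)].copy()
    if len(occ) and occ["arm_framing"].isna().any():
        raise ValueError("occasion with endpoint but no assigned arm")
    occ["endpoint_status"] = classify_endpoints(occ)
    occ = occ[occ["endpoint_status"] != STATUS_EXCLUDED_EARLY]

    rows = []
    keys = [(None, "control")] + [(t, f) for t in TIMINGS for f in FRAMINGS]
    for timing, framing in keys:
        if framing == "control":
            sub = occ[occ["arm_framing"] == "control"]
        else:
            sub = occ[
                (occ["arm_framing"] == framing)
                & (occ["arm_timing"].astype("Float64") == timing)
            ]
        ontime = sub[sub["endpoint_status"] == STATUS_ONTIME]
        b1, b2, b3 = _bin_receipts(ontime["receipt_day"])
        rows.append(
            {
                "timing": _TIMING_LABEL[timing],
                "framing": framing,
                "index_n": len(sub),
                "ontime_n": len(ontime),
                "ontime_prop": round(len(ontime) / len(sub), 2) if len(sub) else 0.0,
                "bin_-14_0": b1,
                "bin_0_7": b2,
                "bin_7_28": b3,
            }
        )
    out = pd.DataFrame(rows)
    totals = out.drop(columns=["timing", "framing", "ontime_prop"]).sum()
    totals["timing"], totals["framing"] = "Total", ""
    totals["ontime_prop"] = (
        round(totals["ontime_n"] / totals["index_n"], 2) if totals["index_n"] else 0.0
    )
    return pd.concat([out, totals.to_frame().T], ignore_index=True)[out.columns]


def exclusion_summary(occasions: pd.DataFrame) -> Dict:
    """Early-vaccination exclusions over all scheduled occasions, overall and
    by schedule point (display percentages rounded to integers)."""
    status = classify_endpoints(occasions)
    excluded = occasions[status == STATUS_EXCLUDED_EARLY]
    total = len(occasions)
    n_exc = len(excluded)
    by_point = (
        excluded.groupby("schedule_point").size().sort_index()
        if n_exc
        else pd.Series(dtype=int)
    )
    return {
        "total_scheduled": total,
        "excluded_early": n_exc,
        "excluded_pct": int(round(100 * n_exc / total)) if total else 0,
        "by_schedule_point": by_point.to_dict(),
        "by_schedule_point_pct": {
            int(s): int(round(100 * c / n_exc)) for s, c in by_point.items()
        }
        if n_exc
        else {},
    }


def format_or_cell(median: float, lo: float, hi: float, pr: float) -> str:
    """Printed style: ``1.29 (1.06, 1.55) 0.99``."""
    return f"{median:.2f} ({lo:.2f}, {hi:.2f}) {pr:.2f}"


def table_two(summaries: Dict[str, pd.DataFrame],
              pooled: Optional[Dict[str, Tuple[float, float, float, float]]] = None
              ) -> pd.DataFrame:
    """Odds-ratio grid by timing x framing x model structure.

    ``summaries`` maps structure name -> arm_summary frame (per-arm rows).
    ``pooled`` optionally maps structure -> (median, lo, hi, pr) for the
    all-arms cell of the shared model. Cells a structure does not define
    carry an explicit missing marker.
    """
    structures = ("full", "no_interaction", "timing_only", "framing_only", "shared")
    row_keys = [("All timings", "All framings")]
    row_keys += [("All timings", f) for f in FRAMINGS]
    for t in TIMINGS:
        row_keys.append((_TIMING_LABEL[t], "All framings"))
        row_keys += [(_TIMING_LABEL[t], f) for f in FRAMINGS]

    def cell(structure: str, timing_label: str, framing: str) -> str:
        summ = summaries.get(structure)
        is_margin_t = timing_label == "All timings"
        is_margin_f = framing == "All framings"
        if structure == "shared":
            if not (is_margin_t and is_margin_f):
                return "—"
            if pooled and structure in pooled:
                return format_or_cell(*pooled[structure])
            if summ is not None and len(summ):
                r = summ.iloc[0]
                return format_or_cell(r.median_or, r.cri_low, r.cri_high, r.pr_gt_1)
            return "·"
        if structure == "timing_only":
            if is_margin_t or not is_margin_f:
                return "—"
        elif structure == "framing_only":
            if is_margin_f or not is_margin_t:
                return "—"
        elif is_margin_t or is_margin_f:  # full / no_interaction
            return "—"
        if summ is None:
            return "·"  # explicit gap: structure not fitted
        arm = _first_arm_with(
            summ,
            framing=None if is_margin_f else framing,
            timing=None if is_margin_t else _timing_from_label(timing_label),
        )
        return _cell_from_row(summ.loc[arm]) if arm else "·"

    data = {
        s: [cell(s, tl, f) for tl, f in row_keys] for s in structures
    }
    idx = pd.MultiIndex.from_tuples(row_keys, names=["timing", "framing"])
    return pd.DataFrame(data, index=idx)


def _timing_from_label(label: str) -> int:
    for t, l in _TIMING_LABEL.items():
        if l == label and t is not None:
            return t
    raise ValueError(label)


def _first_arm_with(summ: pd.DataFrame, framing: str = None, timing: int = None):
    for arm in summ.index:
        f, _, rest = arm.partition("@day")
        if framing is not None and f != framing:
            continue
        if timing is not None and rest and int(rest) != timing:
            continue
        return arm
    return None


def _cell_from_row(r) -> str:
    return format_or_cell(r.median_or, r.cri_low, r.cri_high, r.pr_gt_1)


def table_to_markdown(table: pd.DataFrame) -> str:
    return table.to_markdown()


def receipt_day_summary(occasions: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary of day of receipt relative to due, by arm."""
    occ = occasions.copy()
    occ["endpoint_status"] = classify_endpoints(occ)
    occ = occ.dropna(subset=["receipt_day"])
    g = occ.groupby(["arm_framing", "arm_timing"], dropna=False)["receipt_day"]
    return g.agg(["count", "mean", "median", "min", "max"]).reset_index()
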