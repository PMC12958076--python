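"""Interim triggers, response-adaptive allocation, and stopping rules.

The first interim analysis fires once 1,500 index occasions have completed
their 28-day follow-up; later interims fire after every additional 500.
At each interim the reminder-arm allocation targets are recomputed with
weights proportional to

    w_a = sqrt( Pr(best)_a * Var(log-odds)_a / n_a )

(the square root applying to the whole product; a config switch selects the
sqrt-of-Pr(best)-only variant). The control arm keeps a fixed 1/5 target
until the superiority rule fires: the pooled any-reminder effect, or any
single reminder arm, attains posterior Pr(OR > 1) at or above the decision
threshold, after which control allocation drops to zero for good.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import DecisionThresholds
from .randomisation import CONTROL_TARGET

FIRST_INTERIM_AT = 1500
INTERIM_EVERY = 500


@dataclass(frozen=True)
class InterimDecision:
    """Outcome of one interim analysis."""

    analysis_index: int
    n_index_complete: int
    new_targets: Dict[str, float]
    control_dropped: bool
    effectiveness_declared: bool
    trigger_arm_or_pooled: Optional[str] = None
    decision_statistic: float = float("nan")


def check_interim_trigger(n_index_complete: int, analyses_done: int) -> bool:
    """True once the accrued completed index occasions reach the next
    scheduled interim (1500, 2000, 2500, ...)."""
    if n_index_complete < 0 or analyses_done < 0:
        raise ValueError("counts must be nonnegative")
    return n_index_complete >= FIRST_INTERIM_AT + INTERIM_EVERY * analyses_done


def compute_rar_targets(
    summary: pd.DataFrame,
    control_active: bool,
    sqrt_of_product: bool = True,
    floor: float = 0.0,
) -> pd.Series:
    """Reminder-arm allocation targets from a posterior arm summary.

    ``summary`` must carry columns pr_best, var_logodds and n (one row per
    active reminder arm, every n >= 1). While control is active the
    reminder targets share mass 1 - 1/5 and the returned series includes a
    ``control`` entry of exactly 1/5; afterwards they normalise to 1.
    """
    for col in ("pr_best", "var_logodds", "n"):
        if col not in summary.columns:
            raise ValueError(f"summary lacks column {col!r}")
    if (summary["n"] < 1).any():
        raise ValueError("every active arm needs n >= 1 before RAR applies")
    pi = summary["pr_best"].to_numpy(dtype=float)
    v = summary["var_logodds"].to_numpy(dtype=float)
    n = summary["n"].to_numpy(dtype=float)
    if sqrt_of_product:
        w = np.sqrt(pi * v / n)
    else:
        w = np.sqrt(pi) * v / n
    if w.sum() <= 0:
        # degenerate posterior; fall back to equal weights
        w = np.ones_like(w)
    if floor > 0:
        w = np.maximum(w / w.sum(), floor)
    share = 1.0 - CONTROL_TARGET if control_active else 1.0
    targets = pd.Series(share * w / w.sum(), index=summary.index)
    if control_active:
        targets = pd.concat([pd.Series({"control": CONTROL_TARGET}), targets])
    return targets


def apply_stopping_rules(
    arm_summary: pd.DataFrame,
    pooled_pr_gt_1: float,
    thresholds: DecisionThresholds,
    analysis_index: int,
    n_index_complete: int,
    control_dropped: bool,
    sqrt_of_product: bool = True,
    floor: float = 0.0,
) -> InterimDecision:
    """Evaluate the superiority/stopping rule and compute new targets.

    ``arm_summary`` comes from the primary (full) model, ``pooled_pr_gt_1``
    from the shared model. Control discontinuation is absorbing: once
    ``control_dropped`` is True it stays True and the control target is 0.
    """
    per_arm = arm_summary["pr_gt_1"]
    stat = float(max(pooled_pr_gt_1, per_arm.max()))
    declared = control_dropped
    trigger = None
    if not control_dropped:
        if pooled_pr_gt_1 >= thresholds.superiority_prob:
            declared, trigger = True, "pooled"
        elif per_arm.max() >= thresholds.superiority_prob:
            declared, trigger = True, str(per_arm.idxmax())
    dropped = control_dropped or declared
    targets = compute_rar_targets(
        arm_summary, control_active=not dropped,
        sqrt_of_product=sqrt_of_product, floor=floor,
    )
    if dropped and "control" not in targets.index:
        targets = pd.concat([pd.Series({"control": 0.0}), targets])
    return InterimDecision(
        analysis_index=analysis_index,
        n_index_complete=n_index_complete,
        new_targets=targets.to_dict(),
        control_dropped=dropped,
        effectiveness_declared=declared,
        trigger_arm_or_pooled=trigger,
        decision_statistic=stat,
    )
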