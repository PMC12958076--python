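"""Virtual-trial orchestration and operating characteristics.

One virtual trial replays the real workflow day by day: parents arrive as a
Poisson stream, each is randomised once by the mass-weighted urn at their
first screened occasion, receipt days for all of their children's occasions
are simulated under the assigned arm, and each parent's index occasion
(first SMS-eligible) enters the primary analysis once its 28-day follow-up
is complete. Interim analyses fire at 1,500 completed index occasions and
then every 500, refitting the full and shared models, applying the
superiority/stopping rule and response-adaptive retargeting, and (once
declared) dropping control allocation for good.

Operating characteristics — the declare rate under a scenario — are
estimated over independently seeded replicates. Threshold calibration under
the null exploits the fact that, before any declaration fires, the trial
trajectory does not depend on the threshold: one batch of null replicates
run with an unreachable threshold yields each replicate's running-maximum
decision statistic, from which the declare rate at every candidate
threshold follows at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adaptation import (
    InterimDecision,
    apply_stopping_rules,
    check_interim_trigger,
)
from .arms import ARMS
from .config import DecisionThresholds, ScenarioConfig
from .model import OnTimeLogisticModel
from .population import ReceiptSimulator, generate_population
from .randomisation import (
    DEFAULT_ALPHA_URN,
    assign_arm,
    drop_arm,
    init_allocation,
    retarget,
)
from .schedule import LATE_CUTOFF

@dataclass
class TrialResult:
    """Outcome of one virtual trial replicate."""

    seed: int
    total_randomised: int
    n_assigned: Dict[str, int]
    n_index: Dict[str, int]
    n_index_ontime: Dict[str, int]
    interims: List[InterimDecision]
    declared_effective: bool
    declare_analysis_index: Optional[int]
    max_decision_statistic: float
    final_summary: Optional[pd.DataFrame] = None
    final_pooled_pr: Optional[float] = None
    occasions: Optional[pd.DataFrame] = None

    @property
    def n_interims(self) -> int:
        return len(self.interims)


@dataclass
class OperatingCharacteristics:
    """Declare-rate and allocation aggregates over replicate trials."""

    scenario_label: str
    n_replicates: int
    declare_rate: float
    declare_rate_mcse: float
    mean_total_randomised: float
    mean_allocation: pd.Series
    allocation_quantiles: Optional[pd.DataFrame]
    threshold: Optional[float]
    max_statistics: np.ndarray

    def summary(self) -> str:
        lines = [
            f"Operating characteristics — {self.scenario_label}",
            f"replicates: {self.n_replicates}   threshold: {self.threshold}",
            f"declare rate: {self.declare_rate:.3f} (MCSE {self.declare_rate_mcse:.3f})",
            f"mean randomised: {self.mean_total_randomised:.0f}",
            "mean allocation share by arm:",
        ]
        for arm, share in self.mean_allocation.items():
            lines.append(f"  {arm:<18}{share:.4f}")
        return "\n".join(lines)


@dataclass
class CalibrationResult:
    """Null-calibration of the superiority threshold over a grid."""

    grid: np.ndarray
    declare_rates: np.ndarray
    threshold: Optional[float]
    alpha: float
    n_replicates: int
    max_statistics: np.ndarray

    @property
    def success(self) -> bool:
        return self.threshold is not None


class _IndexStore:
    """Growable arrays of completed-or-pending index occasions."""

    def __init__(self):
        self.parent_id: List[int] = []
        self.clinic_id: List[int] = []
        self.schedule_point: List[int] = []
        self.due: List[int] = []
        self.receipt: List[float] = []
        self.epoch: List[int] = []
        self.framing: List[str] = []
        self.timing: List[float] = []
        self.complete_day: List[int] = []

    def add(self, parent, clinic, point, due, receipt, epoch, framing, timing):
        self.parent_id.append(parent)
        self.clinic_id.append(clinic)
        self.schedule_point.append(point)
        self.due.append(due)
        self.receipt.append(receipt)
        self.epoch.append(epoch)
        self.framing.append(framing)
        self.timing.append(timing)
        self.complete_day.append(due + LATE_CUTOFF)

    def frame(self, as_of_day: Optional[int] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "occasion_id": np.arange(len(self.parent_id)),
                "parent_id": np.asarray(self.parent_id),
                "child_id": np.asarray(self.parent_id),
                "clinic_id": np.asarray(self.clinic_id),
                "schedule_point": np.asarray(self.schedule_point),
                "due_date": np.asarray(self.due),
                "receipt_day": np.asarray(self.receipt, dtype=float),
                "arm_framing": np.asarray(self.framing, dtype=object),
                "arm_timing": np.asarray(self.timing, dtype=float),
                "epoch": np.asarray(self.epoch),
                "is_index": np.ones(len(self.parent_id), dtype=bool),
            }
        )
        if as_of_day is not None:
            df = df[np.asarray(self.complete_day) <= as_of_day]
        return df


def run_virtual_trial(
    config: ScenarioConfig,
    thresholds: Optional[DecisionThresholds] = DecisionThresholds(),
    seed: int = 0,
    engine: str = "laplace",
    n_draws: int = 4000,
    alpha_urn: float = DEFAULT_ALPHA_URN,
    rar_sqrt_of_product: bool = True,
    rar_floor: float = 0.0,
    stop_on_declare: bool = False,
    final_analysis: bool = True,
    adaptation_enabled: bool = True,
    interim_analyses: bool = True,
    record_occasions: bool = False,
) -> TrialResult:
    """Simulate one complete adaptive trial. Deterministic under ``seed``.

    ``thresholds=None`` runs the trial with an unreachable superiority
    threshold (no declaration can fire) while still recording the decision
    statistic at every analysis — the calibration mode.
    """
    rng = np.random.default_rng(seed)
    pop = generate_population(config, rng)
    sim = ReceiptSimulator(config)

    state = init_allocation(alpha_urn=alpha_urn)
    thr = thresholds if thresholds is not None else SimpleNamespace(superiority_prob=2.0)

    n_parents = pop.n_parents
    store = _IndexStore()
    all_rows: List[pd.DataFrame] = []

    if n_parents == 0:
        return TrialResult(
            seed=seed, total_randomised=0,
            n_assigned={a.label: 0 for a in ARMS},
            n_index={a.label: 0 for a in ARMS},
            n_index_ontime={a.label: 0 for a in ARMS},
            interims=[], declared_effective=False, declare_analysis_index=None,
            max_decision_statistic=float("nan"),
            occasions=store.frame() if record_occasions else None,
        )

    # occasion arrays, parent-major (generation order)
    occ = pop.occasions
    o_parent = occ["parent_id"].to_numpy()
    o_point = occ["schedule_point"].to_numpy()
    o_due = occ["due_date"].to_numpy()
    o_epoch = occ["epoch"].to_numpy()
    o_child = occ["child_id"].to_numpy()
    o_codes = sim.point_codes(o_point)
    parent_ptr = np.searchsorted(o_parent, np.arange(n_parents + 1))
    clinic_of_parent = np.array([p.clinic_id for p in pop.parents])
    arrivals = pop.arrival_days

    end_day = int(o_due.max()) + LATE_CUTOFF + 1
    completions = np.zeros(end_day + 2, dtype=int)

    arm_lor = np.array(
        [0.0] + [config.arm_log_or[a] for a in ARMS[1:]]
    )

    interims: List[InterimDecision] = []
    declared = False
    declare_at: Optional[int] = None
    max_stat = -np.inf
    analyses_done = 0
    n_complete = 0
    next_parent = 0
    warm: Dict[str, Optional[np.ndarray]] = {"full": None, "shared": None}

    def run_analysis(day: Optional[int], analysis_index: int) -> Tuple[InterimDecision, pd.DataFrame, float]:
        nonlocal max_stat
        df = store.frame(as_of_day=day)
        full_res = _fit(df, "full", engine, n_draws, rng, warm, "full")
        shared_res = _fit(df, "shared", engine, n_draws, rng, warm, "shared")
        full_summary = full_res.arm_summary()
        pooled_pr = shared_res.pooled_pr_gt_1()
        decision = apply_stopping_rules(
            full_summary,
            pooled_pr,
            thr,
            analysis_index=analysis_index,
            n_index_complete=len(df),
            control_dropped=declared,
            sqrt_of_product=rar_sqrt_of_product,
            floor=rar_floor,
        )
        max_stat = max(max_stat, decision.decision_statistic)
        return decision, full_summary, pooled_pr

    day = 0
    while day <= end_day:
        n_complete += int(completions[day])

        # interim analyses scheduled for today, in order
        while interim_analyses and check_interim_trigger(n_complete, analyses_done):
            decision, _, _ = run_analysis(day, analyses_done + 1)
            analyses_done += 1
            interims.append(decision)
            newly_declared = decision.effectiveness_declared and not declared
            if newly_declared:
                declared = True
                declare_at = decision.analysis_index
                drop_arm(state, ARMS[0])
            if adaptation_enabled:
                t = np.array([decision.new_targets.get(a.label, 0.0) for a in ARMS])
                active_sum = t[state.active].sum()
                if active_sum > 0:
                    retarget(state, np.where(state.active, t / active_sum, 0.0))
            if stop_on_declare and declared:
                day = end_day + 1
                break
        if day > end_day:
            break

        # today's enrolments: sequential urn draws, then one batched
        # receipt simulation for all of today's occasions
        batch: List[Tuple[int, int]] = []
        while next_parent < n_parents and arrivals[next_parent] <= day:
            p = next_parent
            next_parent += 1
            arm = assign_arm(state, str(p), rng)
            batch.append((p, state.arms.index(arm)))
        if batch:
            pids = np.array([b[0] for b in batch])
            karr = np.array([b[1] for b in batch])
            lo = parent_ptr[pids]
            hi = parent_ptr[pids + 1]
            counts = hi - lo
            rows = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi)])
            row_parent_pos = np.repeat(np.arange(len(batch)), counts)
            receipts = sim.draw(
                o_codes[rows],
                o_epoch[rows],
                arm_lor[karr][row_parent_pos],
                pop.clinic_effects[clinic_of_parent[pids]][row_parent_pos],
                pop.parent_effects[pids][row_parent_pos],
                rng,
            )
            with np.errstate(invalid="ignore"):
                eligible = ~(receipts < -14)
            offset = 0
            for bi, (p, k) in enumerate(batch):
                m = counts[bi]
                sl = slice(offset, offset + m)
                offset += m
                if not eligible[sl].any():
                    continue
                rr = rows[sl]
                order = np.lexsort((o_child[rr], o_due[rr]))
                j = order[np.argmax(eligible[sl][order])]
                arm = ARMS[k]
                store.add(
                    p, int(clinic_of_parent[p]), int(o_point[rr[j]]),
                    int(o_due[rr[j]]), float(receipts[sl][j]), int(o_epoch[rr[j]]),
                    arm.framing,
                    float(arm.timing) if arm.timing is not None else np.nan,
                )
                cd = int(o_due[rr[j]]) + LATE_CUTOFF
                if cd <= end_day:
                    completions[cd] += 1
            if record_occasions:
                block = occ.iloc[rows].copy()
                block["receipt_day"] = pd.array(
                    [pd.NA if np.isnan(r) else int(r) for r in receipts], dtype="Int64"
                )
                arm_objs = [ARMS[k] for k in karr[row_parent_pos]]
                block["arm_framing"] = pd.array(
                    [a.framing for a in arm_objs], dtype="string"
                )
                block["arm_timing"] = pd.array(
                    [a.timing if a.timing is not None else pd.NA for a in arm_objs],
                    dtype="Int64",
                )
                all_rows.append(block)
        day += 1

    final_summary = None
    final_pooled = None
    if (final_analysis and interim_analyses and len(store.parent_id) >= 2
            and not (stop_on_declare and declared)):
        decision, final_summary, final_pooled = run_analysis(None, analyses_done + 1)
        interims.append(decision)
        if decision.effectiveness_declared and not declared:
            declared = True
            declare_at = decision.analysis_index

    idx = store.frame()
    n_index = {a.label: 0 for a in ARMS}
    n_ontime = {a.label: 0 for a in ARMS}
    if len(idx):
        lab = np.where(
            idx["arm_framing"].to_numpy() == "control",
            "control",
            [
                f"{f}@day{'+' if t > 0 else ''}{int(t)}" if np.isfinite(t) else "control"
                for f, t in zip(idx["arm_framing"], idx["arm_timing"])
            ],
        )
        ontime = (idx["receipt_day"] >= -14) & (idx["receipt_day"] <= 28)
        for l, o in zip(lab, ontime.fillna(False)):
            n_index[l] += 1
            n_ontime[l] += int(o)

    occasions_out = None
    if record_occasions and all_rows:
        occasions_out = pd.concat(all_rows, ignore_index=True)
        from .schedule import mark_index_occasions

        occasions_out = mark_index_occasions(occasions_out)

    return TrialResult(
        seed=seed,
        total_randomised=int(state.n_assigned.sum()),
        n_assigned={a.label: int(state.n_assigned[i]) for i, a in enumerate(ARMS)},
        n_index=n_index,
        n_index_ontime=n_ontime,
        interims=interims,
        declared_effective=declared,
        declare_analysis_index=declare_at,
        max_decision_statistic=float(max_stat) if np.isfinite(max_stat) else float("nan"),
        final_summary=final_summary,
        final_pooled_pr=final_pooled,
        occasions=occasions_out,
    )


def _fit(df, structure, engine, n_draws, rng, warm, key):
    model = OnTimeLogisticModel.from_dataframe(df, structure=structure, unit="index")
    start = None
    sigma_start = None
    prev = warm.get(key)
    if prev is not None:
        names = model.design.names
        start = np.zeros(model.design.X.shape[1] + model.design.n_clinics)
        prev_names, prev_theta, prev_sigma = prev
        lookup = {n: i for i, n in enumerate(prev_names)}
        for i, n in enumerate(names):
            if n in lookup:
                start[i] = prev_theta[lookup[n]]
        sigma_start = (prev_sigma, 0.15)
    res = model.fit(
        engine=engine, n_draws=n_draws, seed=int(rng.integers(2**31 - 1)),
        start=start, sigma_start=sigma_start if engine == "laplace" else None,
    )
    warm[key] = (model.design.names, res.mode[: len(model.design.names)], res.sigma_clinic)
    return res


def estimate_oc(
    config: ScenarioConfig,
    thresholds: Optional[DecisionThresholds],
    n_replicates: int = 200,
    base_seed: int = 0,
    scenario_label: str = "scenario",
    stop_on_declare: bool = True,
    **trial_kwargs,
) -> OperatingCharacteristics:
    """Estimate declare rate and allocation behaviour over seeded replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = np.random.default_rng(base_seed).integers(2**31 - 1, size=n_replicates)
    declares = np.zeros(n_replicates, dtype=bool)
    totals = np.zeros(n_replicates)
    alloc = np.zeros((n_replicates, len(ARMS)))
    stats = np.zeros(n_replicates)
    for i, s in enumerate(seeds):
        res = run_virtual_trial(
            config, thresholds, seed=int(s), stop_on_declare=stop_on_declare,
            **trial_kwargs,
        )
        declares[i] = res.declared_effective
        totals[i] = res.total_randomised
        stats[i] = res.max_decision_statistic
        tot = max(res.total_randomised, 1)
        alloc[i] = [res.n_assigned[a.label] / tot for a in ARMS]
    rate = float(declares.mean())
    labels = [a.label for a in ARMS]
    quantiles = pd.DataFrame(
        np.quantile(alloc, [0.1, 0.5, 0.9], axis=0).T,
        index=labels, columns=["q10", "q50", "q90"],
    )
    return OperatingCharacteristics(
        scenario_label=scenario_label,
        n_replicates=n_replicates,
        declare_rate=rate,
        declare_rate_mcse=float(np.sqrt(rate * (1 - rate) / n_replicates)),
        mean_total_randomised=float(totals.mean()),
        mean_allocation=pd.Series(alloc.mean(axis=0), index=labels),
        allocation_quantiles=quantiles,
        threshold=(thresholds.superiority_prob if thresholds is not None else None),
        max_statistics=stats,
    )


def calibrate_threshold(
    config_null: ScenarioConfig,
    grid: Sequence[float] = (0.95, 0.97, 0.98, 0.99, 0.995, 0.9975, 0.999, 0.9995, 0.9999),
    n_replicates: int = 200,
    base_seed: int = 0,
    alpha: float = 0.05,
    **trial_kwargs,
) -> CalibrationResult:
    """Find the smallest grid threshold controlling the null declare rate.

    Runs null replicates once with an unreachable threshold, recording each
    replicate's maximum decision statistic over all analyses; the declare
    rate at any candidate threshold is then the fraction of maxima at or
    above it (exact, because the pre-declaration trajectory is
    threshold-free). Returns an explicit failure (``threshold=None``) if no
    grid point controls the rate.
    """
    oc = estimate_oc(
        config_null, thresholds=None, n_replicates=n_replicates,
        base_seed=base_seed, scenario_label="null calibration",
        stop_on_declare=False, **trial_kwargs,
    )
    grid = np.sort(np.asarray(grid, dtype=float))
    stats = oc.max_statistics
    rates = np.array([(stats >= t).mean() for t in grid])
    ok = np.where(rates <= alpha)[0]
    threshold = float(grid[ok[0]]) if len(ok) else None
    return CalibrationResult(
        grid=grid, declare_rates=rates, threshold=threshold,
        alpha=alpha, n_replicates=n_replicates, max_statistics=stats,
    )
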