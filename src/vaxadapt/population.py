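"""Synthetic population and outcome generation.

Generates clinics (with log-odds random effects), parents (1-4 children,
clinic-nested, with their own random effects), and scheduled vaccine
occasions at the routine schedule points {2, 4, 6, 12, 18, 48} months, then
simulates receipt days under an assigned arm with the same logistic
structure the analysis models assume:

    logit P(on time) = logit(baseline_s) + log-OR(arm) + u_clinic
                       [+ v_parent] + drift * epoch

Early vaccination (receipt more than 14 days before due) is generated as a
separate per-schedule-point mechanism, concentrated at the 2-month point.
On-time receipt days are drawn piecewise-uniformly over the bins (-14,0],
(0,7], (7,28]; late receipts are geometric beyond day 28; a configurable
fraction of failures has no receipt record at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .arms import Arm
from .config import (
    EPOCH_DAYS,
    SCHEDULE_GAPS_DAYS,
    SCHEDULE_POINTS,
    ScenarioConfig,
)

OCCASION_COLUMNS = [
    "occasion_id",
    "parent_id",
    "child_id",
    "clinic_id",
    "schedule_point",
    "due_date",
    "receipt_day",
    "arm_framing",
    "arm_timing",
    "epoch",
    "is_index",
]


@dataclass
class Clinic:
    clinic_id: int
    random_effect: float
    size_weight: float


@dataclass
class Parent:
    parent_id: int
    clinic_id: int
    random_effect: float
    children: List[int]
    opted_out: bool = False


@dataclass
class Population:
    """Container for one generated population (pre-assignment)."""

    clinics: List[Clinic]
    parents: List[Parent]
    occasions: pd.DataFrame
    clinic_effects: np.ndarray
    parent_effects: np.ndarray
    arrival_days: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_parents(self) -> int:
        return len(self.parents)


def generate_population(
    config: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    arrival_days: Optional[Sequence[int]] = None,
) -> Population:
    """Generate clinics, parents, children and scheduled vaccine occasions.

    Parents arrive as a homogeneous daily Poisson process (rate
    ``enrolment_per_day``) truncated at ``n_parents_max``; each is linked to
    one clinic and has 1-4 children. Each child's first occasion falls
    within 28 days of arrival (daily screening finds children due within the
    next four weeks); later occasions follow the schedule-point gaps while
    inside the horizon. Reproducible under a fixed seed.

    ``arrival_days`` overrides the simulated arrival process (one entry per
    parent), which the trial engine uses to keep enrolment and randomisation
    in lock-step.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    clinic_effects = (
        rng.normal(0.0, config.sigma_clinic, size=config.n_clinics)
        if config.sigma_clinic > 0
        else np.zeros(config.n_clinics)
    )
    size_weights = rng.dirichlet(np.full(config.n_clinics, 5.0))
    clinics = [
        Clinic(c, float(clinic_effects[c]), float(size_weights[c]))
        for c in range(config.n_clinics)
    ]

    if arrival_days is None:
        arrival_days = _poisson_arrivals(config, rng)
    n_parents = min(len(arrival_days), config.n_parents_max)
    arrival_days = np.asarray(arrival_days[:n_parents], dtype=int)

    if n_parents == 0:
        empty = pd.DataFrame(columns=OCCASION_COLUMNS)
        return Population(clinics, [], empty, clinic_effects, np.zeros(0), arrival_days)

    parent_clinic = rng.choice(config.n_clinics, size=n_parents, p=size_weights)
    parent_effects = (
        rng.normal(0.0, config.sigma_parent, size=n_parents)
        if config.sigma_parent > 0
        else np.zeros(n_parents)
    )
    n_children = rng.choice(
        np.arange(1, 5), size=n_parents, p=np.asarray(config.family_size_probs)
    )

    entry_p = np.array([config.entry_point_probs[s] for s in SCHEDULE_POINTS])

    # children, vectorised: entry schedule point, first due within 28 days of
    # arrival, later occasions at the schedule gaps while inside the horizon
    child_parent = np.repeat(np.arange(n_parents), n_children)
    total_children = len(child_parent)
    child_ids = np.arange(total_children)
    entry_idx = rng.choice(len(SCHEDULE_POINTS), size=total_children, p=entry_p)
    first_due = arrival_days[child_parent] + rng.integers(0, 28, size=total_children)

    cumgap = np.zeros((len(SCHEDULE_POINTS), len(SCHEDULE_POINTS)), dtype=int)
    for e in range(len(SCHEDULE_POINTS)):
        for j in range(e + 1, len(SCHEDULE_POINTS)):
            cumgap[e, j] = cumgap[e, j - 1] + SCHEDULE_GAPS_DAYS[j - 1]

    J = np.broadcast_to(np.arange(len(SCHEDULE_POINTS)), (total_children, len(SCHEDULE_POINTS)))
    due_grid = first_due[:, None] + cumgap[entry_idx]
    keep = (J >= entry_idx[:, None]) & (due_grid <= config.horizon_days)
    flat = keep.ravel()
    rows_child = np.repeat(child_ids, len(SCHEDULE_POINTS))[flat]
    rows_parent = child_parent[rows_child]
    rows_point = np.asarray(SCHEDULE_POINTS)[J.ravel()[flat]]
    due = due_grid.ravel()[flat].astype(int)

    parents: List[Parent] = []
    child_counter = 0
    for i in range(n_parents):
        kids = list(range(child_counter, child_counter + int(n_children[i])))
        child_counter += int(n_children[i])
        parents.append(Parent(i, int(parent_clinic[i]), float(parent_effects[i]), kids))
    occ = pd.DataFrame(
        {
            "occasion_id": np.arange(len(rows_parent)),
            "parent_id": np.asarray(rows_parent, dtype=int),
            "child_id": np.asarray(rows_child, dtype=int),
            "clinic_id": parent_clinic[np.asarray(rows_parent, dtype=int)].astype(int),
            "schedule_point": np.asarray(rows_point, dtype=int),
            "due_date": due,
            "receipt_day": pd.array([pd.NA] * len(due), dtype="Int64"),
            "arm_framing": pd.array([pd.NA] * len(due), dtype="string"),
            "arm_timing": pd.array([pd.NA] * len(due), dtype="Int64"),
            "epoch": due // EPOCH_DAYS,
            "is_index": np.zeros(len(due), dtype=bool),
        }
    )
    return Population(clinics, parents, occ, clinic_effects, parent_effects, arrival_days)


def _poisson_arrivals(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(config.enrolment_per_day, size=config.horizon_days)
    days = np.repeat(np.arange(config.horizon_days), counts)
    return days[: config.n_parents_max]


def ontime_probability(
    schedule_point: int,
    arm_log_or: float,
    config: ScenarioConfig,
    clinic_effect: float = 0.0,
    parent_effect: float = 0.0,
    epoch: int = 0,
) -> float:
    """Conditional (not-early) on-time probability under the generating model."""
    if schedule_point not in config.baseline_ontime:
        raise ValueError(f"unknown schedule point {schedule_point}")
    eta = (
        logit(config.baseline_ontime[schedule_point])
        + arm_log_or
        + clinic_effect
        + parent_effect
        + config.epoch_drift * epoch
    )
    return float(expit(eta))


class ReceiptSimulator:
    """Pre-compiled per-schedule-point lookups for fast receipt simulation.

    The trial engine calls :meth:`draw` once per enrolment day; everything
    is plain numpy on integer-coded schedule points.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config
        pts = np.asarray(SCHEDULE_POINTS)
        self._points = pts
        self._early_p = np.array([config.early_vax_prob[int(s)] for s in pts])
        self._logit_base = logit(np.array([config.baseline_ontime[int(s)] for s in pts]))
        self._bin_cum = np.cumsum(np.asarray(config.ontime_bin_masses))

    def point_codes(self, points: np.ndarray) -> np.ndarray:
        codes = np.searchsorted(self._points, points)
        bad = (codes >= len(self._points)) | (self._points[np.clip(codes, 0, 5)] != points)
        if bad.any():
            raise ValueError(f"unknown schedule point(s): {set(np.asarray(points)[bad])}")
        return codes

    def draw(
        self,
        point_codes: np.ndarray,
        epochs: np.ndarray,
        arm_log_or: np.ndarray,
        clinic_effect: np.ndarray,
        parent_effect: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        cfg = self.config
        n = len(point_codes)
        receipt = np.full(n, np.nan)
        early = rng.random(n) < self._early_p[point_codes]
        n_early = int(early.sum())
        if n_early:
            receipt[early] = -rng.integers(15, 46, size=n_early).astype(float)

        eta = (
            self._logit_base[point_codes]
            + arm_log_or
            + clinic_effect
            + parent_effect
            + cfg.epoch_drift * epochs
        )
        ontime = (~early) & (rng.random(n) < expit(eta))
        m = int(ontime.sum())
        if m:
            bins = np.searchsorted(self._bin_cum, rng.random(m), side="right")
            day = np.empty(m)
            day[bins == 0] = rng.integers(-14, 1, size=int((bins == 0).sum()))
            day[bins == 1] = rng.integers(1, 8, size=int((bins == 1).sum()))
            day[bins == 2] = rng.integers(8, 29, size=int((bins == 2).sum()))
            receipt[ontime] = day

        late = (~early) & (~ontime)
        k = int(late.sum())
        if k:
            never = rng.random(k) < cfg.p_never_vaccinated
            days = 28.0 + rng.geometric(cfg.late_geometric_p, size=k)
            days[never] = np.nan
            receipt[late] = days
        return receipt


def simulate_receipts(
    occasions: pd.DataFrame,
    arm_log_or: np.ndarray,
    clinic_effect: np.ndarray,
    parent_effect: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised receipt-day simulation for a block of occasions.

    Parameters are per-row arrays aligned with ``occasions``. Returns a float
    array of signed day offsets from the due date, with NaN for occasions
    that have no receipt record.
    """
    sim = ReceiptSimulator(config)
    codes = sim.point_codes(occasions["schedule_point"].to_numpy())
    return sim.draw(
        codes,
        occasions["epoch"].to_numpy(),
        np.asarray(arm_log_or, dtype=float),
        np.asarray(clinic_effect, dtype=float),
        np.asarray(parent_effect, dtype=float),
        rng,
    )


def simulate_receipt(
    occasion,
    arm: Arm,
    config: ScenarioConfig,
    rng: np.random.Generator,
    clinic_effect: float = 0.0,
    parent_effect: float = 0.0,
) -> Optional[int]:
    """Single-occasion receipt draw (scalar convenience over
    :func:`simulate_receipts`). Returns the signed day offset or ``None``."""
    row = pd.DataFrame(
        {
            "schedule_point": [occasion["schedule_point"] if isinstance(occasion, (dict, pd.Series)) else occasion.schedule_point],
            "epoch": [occasion["epoch"] if isinstance(occasion, (dict, pd.Series)) else occasion.epoch],
        }
    )
    lor = 0.0 if arm.is_control else config.arm_log_or.get(arm, 0.0)
    out = simulate_receipts(
        row,
        np.array([lor]),
        np.array([clinic_effect]),
        np.array([parent_effect]),
        config,
        rng,
    )[0]
    return None if np.isnan(out) else int(out)


def assign_and_simulate(
    population: Population,
    arm_of_parent: Dict[int, Arm],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Attach arm labels to every occasion and simulate all receipt days."""
    occ = population.occasions.copy()
    pid = occ["parent_id"].to_numpy()
    arm_list = [arm_of_parent[p] for p in pid]
    occ["arm_framing"] = pd.array([a.framing for a in arm_list], dtype="string")
    occ["arm_timing"] = pd.array(
        [a.timing if a.timing is not None else pd.NA for a in arm_list], dtype="Int64"
    )
    lors = np.array(
        [0.0 if a.is_control else config.arm_log_or[a] for a in arm_list]
    )
    receipt = simulate_receipts(
        occ,
        lors,
        population.clinic_effects[occ["clinic_id"].to_numpy()],
        population.parent_effects[pid],
        config,
        rng,
    )
    occ["receipt_day"] = pd.array(
        [pd.NA if np.isnan(r) else int(r) for r in receipt], dtype="Int64"
    )
    return occ
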