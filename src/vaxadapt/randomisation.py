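"""Mass-weighted urn randomisation with sibling-consistent assignment.

The mass-weighted urn design (MWUD) keeps a nonnegative "mass" per arm. A
fresh parent is assigned arm k with probability proportional to max(m_k, 0)
over the active arms; the winner's mass then loses 1 and every active arm is
replenished by its target probability, so total mass is conserved at the urn
parameter alpha and realised allocations track the targets with bounded
imbalance. A parent already in the assignment log always receives their
logged arm (covering all of their children and later occasions) with no urn
update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .arms import ARM_BY_LABEL, ARMS, Arm, validate_arm

DEFAULT_ALPHA_URN = 4.0

#: Initial allocation of the 13-arm design: 1/5 control, 1/15 each reminder arm.
INITIAL_TARGETS = (1 / 5,) + (1 / 15,) * 12

CONTROL_TARGET = 1 / 5


@dataclass
class AllocationState:
    """Urn state: targets, masses, counts, activity flags and the parent log."""

    arms: Tuple[Arm, ...]
    targets: np.ndarray
    masses: np.ndarray
    alpha_urn: float
    n_assigned: np.ndarray
    active: np.ndarray
    assignment_log: Dict[str, int] = field(default_factory=dict)

    def arm_index(self, arm: Arm) -> int:
        return self.arms.index(arm)

    def check(self) -> None:
        active_sum = float(self.targets[self.active].sum())
        if abs(active_sum - 1.0) > 1e-9:
            raise ValueError(f"active targets sum to {active_sum}, not 1")
        if (self.targets < -1e-12).any():
            raise ValueError("negative target probability")
        if (self.n_assigned < 0).any():
            raise ValueError("negative assignment count")

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "arms": [a.label for a in self.arms],
                "targets": self.targets.tolist(),
                "masses": self.masses.tolist(),
                "alpha_urn": self.alpha_urn,
                "n_assigned": self.n_assigned.tolist(),
                "active": self.active.tolist(),
                "assignment_log": self.assignment_log,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AllocationState":
        d = json.loads(text)
        return cls(
            arms=tuple(ARM_BY_LABEL[l] for l in d["arms"]),
            targets=np.asarray(d["targets"], dtype=float),
            masses=np.asarray(d["masses"], dtype=float),
            alpha_urn=float(d["alpha_urn"]),
            n_assigned=np.asarray(d["n_assigned"], dtype=int),
            active=np.asarray(d["active"], dtype=bool),
            assignment_log={k: int(v) for k, v in d["assignment_log"].items()},
        )


def init_allocation(
    arms: Sequence[Arm] = ARMS,
    targets: Optional[Sequence[float]] = None,
    alpha_urn: float = DEFAULT_ALPHA_URN,
) -> AllocationState:
    """Initialise the urn with masses alpha * target and empty log."""
    arms = tuple(validate_arm(a) if a in ARMS else a for a in arms)
    if targets is None:
        targets = INITIAL_TARGETS if len(arms) == len(ARMS) else None
        if targets is None:
            raise ValueError("targets required for non-standard arm sets")
    t = np.asarray(targets, dtype=float)
    if len(t) != len(arms):
        raise ValueError("one target per arm required")
    if (t < 0).any() or abs(t.sum() - 1.0) > 1e-9:
        raise ValueError("targets must be nonnegative and sum to 1")
    state = AllocationState(
        arms=arms,
        targets=t.copy(),
        masses=alpha_urn * t,
        alpha_urn=float(alpha_urn),
        n_assigned=np.zeros(len(arms), dtype=int),
        active=np.ones(len(arms), dtype=bool),
    )
    state.check()
    return state


def assign_arm(
    state: AllocationState, parent_id: str, rng: np.random.Generator,
    audit=None,
) -> Arm:
    """Assign a parent to an arm, mutating the urn state.

    A previously logged parent receives the identical arm with no urn update
    and no count increment (sibling consistency). A fresh parent triggers a
    mass-weighted draw and the subtract-1/replenish update. ``audit``, if
    given, is a writable text stream receiving one JSON line per fresh
    assignment (parent id, arm, draw probabilities, event index).
    """
    if parent_id is None or parent_id == "":
        raise ValueError("parent_id must be non-empty")
    parent_id = str(parent_id)
    if parent_id in state.assignment_log:
        return state.arms[state.assignment_log[parent_id]]

    all_active = bool(state.active.all())
    if all_active:
        w = np.maximum(state.masses, 0.0)
    else:
        w = np.where(state.active, np.maximum(state.masses, 0.0), 0.0)
    c = np.cumsum(w)
    total = c[-1]
    if total <= 0:
        raise RuntimeError("urn invariant violated: no positive mass on active arms")
    k = int(np.searchsorted(c, rng.random() * total, side="right"))
    k = min(k, len(w) - 1)
    state.masses[k] -= 1.0
    if all_active:
        state.masses += state.targets
    else:
        state.masses[state.active] += state.targets[state.active]
    state.n_assigned[k] += 1
    state.assignment_log[parent_id] = k
    if audit is not None:
        audit.write(json.dumps({
            "event": int(state.n_assigned.sum()),
            "parent_id": parent_id,
            "arm": state.arms[k].label,
            "probs": (w / total).round(6).tolist(),
        }) + "\n")
    return state.arms[k]


def retarget(state: AllocationState, new_targets: Sequence[float]) -> AllocationState:
    """Re-initialise urn masses to alpha * new_target, preserving the log.

    Deactivated arms must have target 0 and can never be reactivated.
    Mutates and returns ``state``.
    """
    t = np.asarray(new_targets, dtype=float)
    if len(t) != len(state.arms):
        raise ValueError("one target per arm required")
    if (t < 0).any():
        raise ValueError("targets must be nonnegative")
    if (t[~state.active] > 0).any():
        raise ValueError("cannot reactivate a dropped arm")
    if abs(t.sum() - 1.0) > 1e-9:
        raise ValueError("targets must sum to 1")
    state.targets = t.copy()
    state.masses = state.alpha_urn * t
    state.check()
    return state


def drop_arm(state: AllocationState, arm: Arm) -> AllocationState:
    """Deactivate an arm (absorbing) and renormalise targets over the rest."""
    k = state.arm_index(arm)
    if not state.active[k]:
        return state
    state.active[k] = False
    t = state.targets.copy()
    t[k] = 0.0
    remaining = t.sum()
    if remaining <= 0:
        raise ValueError("cannot drop the last active arm")
    return retarget(state, t / remaining)
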