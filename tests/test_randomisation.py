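"""Mass-weighted urn: exact arithmetic, balance, sibling consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vaxadapt.arms import ARMS, CONTROL, FRAMINGS, TIMINGS
from vaxadapt.randomisation import (
    INITIAL_TARGETS,
    AllocationState,
    assign_arm,
    drop_arm,
    init_allocation,
    retarget,
)


class _ForcedRng:
    """Stub generator whose uniform draw forces a chosen urn outcome."""

    def __init__(self, value: float):
        self.value = value

    def random(self):
        return self.value


def test_initial_masses_definitional():
    state = init_allocation(alpha_urn=15.0)
    assert state.masses[0] == pytest.approx(3.0)
    assert np.allclose(state.masses[1:], 1.0)
    assert np.all(state.n_assigned == 0)
    assert state.active.all()


def test_initial_margins_by_framing_and_timing():
    """1/5 of allocation per framing, 4/15 per timing."""
    state = init_allocation()
    for f in FRAMINGS:
        mass = sum(t for a, t in zip(ARMS, state.targets) if a.framing == f)
        assert mass == pytest.approx(1 / 5)
    for t in TIMINGS:
        mass = sum(tt for a, tt in zip(ARMS, state.targets) if a.timing == t)
        assert mass == pytest.approx(4 / 15)
    assert state.targets[0] == pytest.approx(1 / 5)


def test_invalid_targets_rejected():
    with pytest.raises(ValueError):
        init_allocation(ARMS, targets=[0.5] * 13)


def test_single_arm_always_assigned():
    state = init_allocation(ARMS[:1], targets=[1.0])
    rng = np.random.default_rng(0)
    assert all(assign_arm(state, str(i), rng) == CONTROL for i in range(20))


def test_sibling_consistency_and_single_count():
    state = init_allocation()
    rng = np.random.default_rng(1)
    a1 = assign_arm(state, "parent-x", rng)
    n_after_first = state.n_assigned.copy()
    a2 = assign_arm(state, "parent-x", rng)
    assert a1 == a2
    np.testing.assert_array_equal(state.n_assigned, n_after_first)


def test_empty_parent_id_rejected():
    state = init_allocation()
    with pytest.raises(ValueError):
        assign_arm(state, "", np.random.default_rng(0))


def test_urn_update_hand_oracle():
    """Two arms, targets (2/3, 1/3), alpha 3: after a forced assignment to
    arm 1, masses are (5/3, 4/3) and the next draw odds are (5/9, 4/9)."""
    arms = ARMS[:2]
    state = init_allocation(arms, targets=[2 / 3, 1 / 3], alpha_urn=3.0)
    np.testing.assert_allclose(state.masses, [2.0, 1.0])
    assign_arm(state, "p1", _ForcedRng(0.0))  # mass-weighted draw lands in arm 1
    np.testing.assert_allclose(state.masses, [2 - 1 + 2 / 3, 1 + 1 / 3])
    w = np.maximum(state.masses, 0)
    np.testing.assert_allclose(w / w.sum(), [5 / 9, 4 / 9])


def test_long_run_convergence_and_balance_bound():
    """Over 15,000 draws at fixed targets the realised proportions match the
    targets within 0.01, and |n_k - n*rho_k| stays below alpha_urn + 1."""
    state = init_allocation(alpha_urn=4.0)
    rng = np.random.default_rng(99)
    targets = state.targets.copy()
    n = 15_000
    max_dev = 0.0
    for i in range(n):
        assign_arm(state, f"p{i}", rng)
        dev = np.abs(state.n_assigned - (i + 1) * targets).max()
        max_dev = max(max_dev, dev)
    props = state.n_assigned / n
    assert np.abs(props - targets).max() < 0.01
    assert max_dev <= state.alpha_urn + 1


def test_control_fraction_in_windows():
    """While control is active, every window of 1,000 fresh assignments puts
    within 0.03 of 1/5 of parents on control."""
    state = init_allocation()
    rng = np.random.default_rng(5)
    draws = np.array(
        [assign_arm(state, f"p{i}", rng).is_control for i in range(5000)]
    )
    for start in range(0, 4000, 1000):
        frac = draws[start:start + 1000].mean()
        assert abs(frac - 0.2) < 0.03


def test_retarget_preserves_log_and_deactivation_is_final():
    state = init_allocation()
    rng = np.random.default_rng(2)
    for i in range(50):
        assign_arm(state, f"p{i}", rng)
    log_before = dict(state.assignment_log)
    n_before = state.n_assigned.copy()

    drop_arm(state, CONTROL)
    assert state.targets[0] == 0.0
    assert not state.active[0]
    assert state.assignment_log == log_before
    np.testing.assert_array_equal(state.n_assigned, n_before)

    # control is never drawn again
    fresh = [assign_arm(state, f"q{i}", rng) for i in range(10_000)]
    assert not any(a.is_control for a in fresh)

    # reactivation attempt is an error
    with pytest.raises(ValueError, match="reactivate"):
        retarget(state, INITIAL_TARGETS)


def test_retarget_identity_resets_masses():
    state = init_allocation(alpha_urn=4.0)
    rng = np.random.default_rng(3)
    for i in range(37):
        assign_arm(state, f"p{i}", rng)
    retarget(state, INITIAL_TARGETS)
    np.testing.assert_allclose(state.masses, 4.0 * np.asarray(INITIAL_TARGETS))


def test_two_arm_balance_bound():
    """Equal targets over two arms: after 1,000 draws the arm counts differ
    from 500 by at most alpha_urn + 1."""
    state = init_allocation(ARMS[:2], targets=[0.5, 0.5], alpha_urn=4.0)
    rng = np.random.default_rng(11)
    for i in range(1000):
        assign_arm(state, f"p{i}", rng)
    assert abs(state.n_assigned[0] - 500) <= state.alpha_urn + 1


def test_json_roundtrip():
    state = init_allocation()
    rng = np.random.default_rng(4)
    for i in range(25):
        assign_arm(state, f"p{i}", rng)
    back = AllocationState.from_json(state.to_json())
    assert back.arms == state.arms
    np.testing.assert_allclose(back.masses, state.masses)
    np.testing.assert_array_equal(back.n_assigned, state.n_assigned)
    assert back.assignment_log == state.assignment_log


@settings(max_examples=25, deadline=None)
@given(
    weights=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=13),
    seed=st.integers(0, 2**20),
)
def test_urn_mass_conservation_and_log_function(weights, seed):
    """Total urn mass stays at alpha and the assignment log never maps one
    parent to two arms, for arbitrary target vectors."""
    targets = np.asarray(weights) / np.sum(weights)
    arms = ARMS[: len(targets)]
    state = init_allocation(arms, targets=targets, alpha_urn=4.0)
    rng = np.random.default_rng(seed)
    seen = {}
    for i in range(300):
        pid = f"p{i % 120}"  # repeats exercise the sibling path
        arm = assign_arm(state, pid, rng)
        assert seen.setdefault(pid, arm) == arm
        assert state.masses.sum() == pytest.approx(4.0, abs=1e-9)


def test_assignment_audit_log_lines():
    """One JSON line per fresh assignment; sibling re-use writes nothing."""
    import io
    import json

    buf = io.StringIO()
    state = init_allocation()
    rng = np.random.default_rng(0)
    for i in range(5):
        assign_arm(state, f"p{i}", rng, audit=buf)
    assign_arm(state, "p0", rng, audit=buf)
    lines = [json.loads(l) for l in buf.getvalue().splitlines()]
    assert len(lines) == 5
    for rec in lines:
        assert sum(rec["probs"]) == pytest.approx(1.0, abs=1e-4)
        assert rec["arm"] in {a.label for a in ARMS}
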