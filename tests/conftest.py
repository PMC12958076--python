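"""Shared fixtures: small simulated datasets built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vaxadapt.arms import ARMS
from vaxadapt.config import ScenarioConfig
from vaxadapt.population import assign_and_simulate, generate_population
from vaxadapt.randomisation import assign_arm, init_allocation
from vaxadapt.schedule import mark_index_occasions


def make_index_frame(
    rng: np.random.Generator,
    n: int,
    p_control: float = 0.45,
    arm_log_or: dict | None = None,
    n_clinics: int = 4,
    sigma_clinic: float = 0.0,
    arms=None,
) -> pd.DataFrame:
    """Directly simulated index-occasion table (no trial machinery): arms
    uniform over the requested set, outcomes Bernoulli from the logistic
    model at a single schedule point and epoch."""
    from scipy.special import expit, logit

    arms = list(arms) if arms is not None else list(ARMS)
    arm_log_or = arm_log_or or {}
    arm_idx = rng.integers(0, len(arms), size=n)
    clinic = rng.integers(0, n_clinics, size=n)
    u = rng.normal(0, sigma_clinic, size=n_clinics) if sigma_clinic > 0 else np.zeros(n_clinics)
    lors = np.array([0.0 if a.is_control else arm_log_or.get(a, 0.0) for a in arms])
    eta = logit(p_control) + lors[arm_idx] + u[clinic]
    y = rng.random(n) < expit(eta)
    receipt = np.where(y, 10, np.nan)
    return pd.DataFrame(
        {
            "occasion_id": np.arange(n),
            "parent_id": np.arange(n),
            "child_id": np.arange(n),
            "clinic_id": clinic,
            "schedule_point": 12,
            "due_date": 100,
            "receipt_day": receipt,
            "arm_framing": [arms[i].framing for i in arm_idx],
            "arm_timing": [np.nan if arms[i].timing is None else float(arms[i].timing)
                           for i in arm_idx],
            "epoch": 3,
            "is_index": True,
        }
    )


@pytest.fixture(scope="session")
def small_trial_occasions() -> pd.DataFrame:
    """A modest simulated occasion table with fixed-target randomisation."""
    cfg = ScenarioConfig(n_parents_max=2500, n_clinics=8, seed=7).with_uniform_or(1.4)
    rng = np.random.default_rng(7)
    pop = generate_population(cfg, rng)
    state = init_allocation()
    arm_of = {p.parent_id: assign_arm(state, str(p.parent_id), rng) for p in pop.parents}
    occ = assign_and_simulate(pop, arm_of, cfg, rng)
    return mark_index_occasions(occ)
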