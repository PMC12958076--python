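"""One-shot analysis across the five pre-specified model structures."""

from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from .config import PriorSpec
from .model import STRUCTURES, OnTimeLogisticModel, OnTimeResults


def fit_all_structures(
    occasions: pd.DataFrame,
    unit: str = "index",
    engine: str = "mcmc",
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    priors: PriorSpec = PriorSpec(),
) -> Dict[str, OnTimeResults]:
    """Fit the full and all four reduced structures to one dataset."""
    out: Dict[str, OnTimeResults] = {}
    for i, structure in enumerate(STRUCTURES):
        model = OnTimeLogisticModel.from_dataframe(
            occasions, structure=structure, unit=unit, priors=priors
        )
        out[structure] = model.fit(
            engine=engine, n_draws=n_draws,
            seed=None if seed is None else seed + i,
        )
    return out


def summaries_for_report(results: Dict[str, OnTimeResults]):
    """Arm summaries plus the pooled cell, shaped for ``reporting.table_two``."""
    summaries = {s: r.arm_summary() for s, r in results.items()}
    pooled = None
    if "shared" in results:
        import numpy as np

        lo = results["shared"].pooled_logor_draws()
        q = np.percentile(lo, [2.5, 50.0, 97.5])
        pooled = {
            "shared": (
                float(np.exp(q[1])), float(np.exp(q[0])), float(np.exp(q[2])),
                float((lo > 0).mean()),
            )
        }
    return summaries, pooled
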