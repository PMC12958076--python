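"""Plots hanging off the results objects (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_arm_posteriors(results, ax=None):
    """Forest-style plot of per-arm posterior odds ratios (median, 95% CrI)."""
    import matplotlib.pyplot as plt

    summ = results.arm_summary()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(summ) + 1))
    y = np.arange(len(summ))[::-1]
    ax.hlines(y, summ["cri_low"], summ["cri_high"], color="steelblue")
    ax.plot(summ["median_or"], y, "o", color="steelblue")
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(summ.index)
    ax.set_xlabel("odds ratio vs control (log scale)")
    ax.set_xscale("log")
    ax.set_title(f"{results.model.structure} model, {results.engine} engine")
    return ax


def plot_allocation_trajectory(trial_result, ax=None):
    """Stacked target-allocation trajectory over interim analyses."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    interims = trial_result.interims
    if not interims:
        return ax
    arms = sorted(interims[0].new_targets)
    xs = [d.analysis_index for d in interims]
    for arm in arms:
        ax.plot(xs, [d.new_targets.get(arm, 0.0) for d in interims],
                label=arm, lw=1.2 if arm == "control" else 0.8)
    ax.set_xlabel("interim analysis")
    ax.set_ylabel("target allocation probability")
    ax.legend(fontsize=6, ncol=2)
    return ax
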