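"""Bayesian logistic models: design encodings, posterior correctness,
engine agreement, marginal standardisation."""

import numpy as np
import pandas as pd
import pytest

from vaxadapt.arms import ARMS, CONTROL, SMS_ARMS, Arm
from vaxadapt.model import OnTimeLogisticModel, build_design

from conftest import make_index_frame


def _fit(df, structure="shared", **kw):
    model = OnTimeLogisticModel.from_dataframe(df, structure=structure)
    kw.setdefault("engine", "laplace")
    kw.setdefault("n_draws", 4000)
    kw.setdefault("seed", 0)
    return model.fit(**kw)


# -- design ----------------------------------------------------------------

def test_full_design_arm_dimensions(small_trial_occasions):
    """Full factorial block: 4 framing + 3 timing + 12 interaction columns."""
    d = build_design(small_trial_occasions, structure="full")
    framing_cols = [n for n in d.names if n.startswith("framing[")]
    timing_cols = [n for n in d.names if n.startswith("timing[")]
    fx_cols = [n for n in d.names if n.startswith("fx[")]
    assert (len(framing_cols), len(timing_cols), len(fx_cols)) == (4, 3, 12)
    # the arm block spans exactly 12 arm-identifying degrees of freedom
    arm_cols = [d.names.index(c) for c in framing_cols + timing_cols + fx_cols]
    assert np.linalg.matrix_rank(d.X[:, arm_cols]) == 12


def test_shared_design_is_single_any_sms_column(small_trial_occasions):
    d = build_design(small_trial_occasions, structure="shared")
    assert "sms" in d.names
    assert not any(n.startswith("framing[") for n in d.names)
    col = d.X[:, d.names.index("sms")]
    assert set(np.unique(col)) == {0.0, 1.0}


def test_excluded_early_rows_absent_from_design(small_trial_occasions):
    occ = small_trial_occasions.copy()
    # force one index row to be early-vaccinated
    i = occ[occ["is_index"]].index[0]
    occ.loc[i, "receipt_day"] = -30
    d = build_design(occ, structure="shared")
    assert len(d.y) == int(occ["is_index"].sum()) - 1


def test_index_unit_one_row_per_parent(small_trial_occasions):
    d = build_design(small_trial_occasions, structure="shared", unit="index")
    assert len(d.y) == small_trial_occasions["is_index"].sum()


def test_empty_design_is_error():
    df = make_index_frame(np.random.default_rng(0), 10)
    df["receipt_day"] = -30.0  # everything excluded
    with pytest.raises(ValueError, match="no analysable"):
        build_design(df, structure="shared")


def test_missing_arm_label_is_schema_error(small_trial_occasions):
    occ = small_trial_occasions.copy()
    occ["arm_framing"] = occ["arm_framing"].astype("string")
    occ.loc[occ.index[occ["is_index"]][0], "arm_framing"] = pd.NA
    with pytest.raises(ValueError, match="no assigned arm"):
        build_design(occ, structure="shared")


def test_heterogeneity_requires_shared_structure(small_trial_occasions):
    with pytest.raises(ValueError):
        build_design(small_trial_occasions, structure="full",
                     heterogeneity_by_schedule_point=True)
    d = build_design(small_trial_occasions, structure="shared",
                     heterogeneity_by_schedule_point=True)
    assert sum(n.startswith("sms[x") for n in d.names) == len(d.schedule_points)


# -- posterior correctness -------------------------------------------------

def test_shared_two_by_two_matches_sample_log_odds_ratio():
    """SMS 500/1000 vs control 400/1000: posterior median log-OR within
    0.05 of the contingency-table value log(1.5)."""
    rows = []
    for arm, n, k in ((CONTROL, 1000, 400), (Arm("neutral", 0), 1000, 500)):
        for i in range(n):
            rows.append((arm.framing,
                         np.nan if arm.timing is None else float(arm.timing),
                         10.0 if i < k else np.nan))
    df = pd.DataFrame(rows, columns=["arm_framing", "arm_timing", "receipt_day"])
    df["occasion_id"] = df["parent_id"] = df["child_id"] = np.arange(len(df))
    df["clinic_id"] = 0
    df["schedule_point"] = 12
    df["due_date"] = 100
    df["epoch"] = 3
    df["is_index"] = True
    res = _fit(df, "shared", n_draws=10_000)
    sample_logor = np.log((500 * 600) / (500 * 400))
    posterior_med = np.log(res.arm_summary()["median_or"].iloc[0])
    assert abs(posterior_med - sample_logor) < 0.05


def test_null_data_gives_null_centred_posterior():
    """All arm effects zero at n = 20,000: median ORs sit near 1 and the
    per-arm Pr(OR>1) values average near one half. (Individual Pr(OR>1)
    values are close to uniform under the null, so only their mean — not
    each arm's value — is pinned.)"""
    df = make_index_frame(np.random.default_rng(21), 20_000)
    res = _fit(df, "full")
    summ = res.arm_summary()
    assert summ["median_or"].between(0.85, 1.18).all()
    assert 0.3 < summ["pr_gt_1"].mean() < 0.7
    assert summ["pr_gt_1"].between(0.02, 0.98).all()


def test_credible_interval_percentile_oracle():
    """CrI endpoints equal 2.5/97.5 percentiles computed by independent
    sorting arithmetic on the same draws."""
    df = make_index_frame(np.random.default_rng(3), 2000)
    res = _fit(df, "shared")
    logor = res.arm_logor_draws().iloc[:, 0].to_numpy()

    def percentile_by_sorting(x, q):
        s = np.sort(x)
        pos = q / 100 * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    summ = res.arm_summary()
    assert summ["cri_low"].iloc[0] == pytest.approx(
        np.exp(percentile_by_sorting(logor, 2.5)), rel=1e-12)
    assert summ["cri_high"].iloc[0] == pytest.approx(
        np.exp(percentile_by_sorting(logor, 97.5)), rel=1e-12)
    assert (summ["cri_low"] <= summ["median_or"]).all()
    assert (summ["median_or"] <= summ["cri_high"]).all()


def test_pr_best_degenerate_and_symmetric():
    df = make_index_frame(np.random.default_rng(4), 1500)
    res = _fit(df, "full")
    k = res.draws_fixed.shape[1]
    names = res.param_names

    # one arm dominant in every draw
    res.draws_fixed = np.zeros((500, k))
    res.draws_fixed[:, names.index("fx[risk:0]")] = 1.0
    summ = res.arm_summary()
    assert summ.loc["risk@day0", "pr_best"] == 1.0
    assert summ["pr_best"].sum() == pytest.approx(1.0)

    # exchangeable draws: two-arm restriction splits evenly
    rng = np.random.default_rng(5)
    res.draws_fixed = np.zeros((40_000, k))
    res.draws_fixed[:, names.index("fx[risk:0]")] = rng.normal(size=40_000)
    res.draws_fixed[:, names.index("fx[social:0]")] = rng.normal(size=40_000)
    summ = res.arm_summary(active_arms=["risk@day0", "social@day0"])
    assert summ.loc["risk@day0", "pr_best"] == pytest.approx(0.5, abs=0.02)
    assert summ["pr_best"].sum() == pytest.approx(1.0)


def test_pr_best_sums_to_one(small_trial_occasions):
    res = _fit(small_trial_occasions, "full")
    summ = res.arm_summary()
    assert summ["pr_best"].sum() == pytest.approx(1.0, abs=1e-9)
    assert (summ["median_or"] > 0).all()
    assert summ["pr_gt_1"].between(0, 1).all()


# -- marginal standardisation ---------------------------------------------

def test_marginal_difference_zero_when_effects_zero():
    df = make_index_frame(np.random.default_rng(6), 1500)
    res = _fit(df, "shared")
    names = res.param_names
    res.draws_fixed = np.zeros_like(res.draws_fixed)
    res.draws_fixed[:, names.index("intercept")] = -0.5
    out = res.marginal_difference()
    assert np.allclose(out["median"], 0.0)
    assert np.allclose(out["cri_low"], 0.0)


def test_marginal_difference_closed_form():
    """Single schedule point, p0 = 0.45, shared OR = 1.29: the standardised
    difference is 1.29*odds0/(1+1.29*odds0) - 0.45 = 0.064 in every draw."""
    from scipy.special import logit

    df = make_index_frame(np.random.default_rng(7), 1500)
    res = _fit(df, "shared")
    names = res.param_names
    res.draws_fixed = np.zeros_like(res.draws_fixed)
    res.draws_fixed[:, names.index("intercept")] = logit(0.45)
    res.draws_fixed[:, names.index("sms")] = np.log(1.29)
    odds = 0.45 / 0.55 * 1.29
    expected = odds / (1 + odds) - 0.45
    out = res.marginal_difference()
    assert out.loc["pooled", "median"] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.064, abs=1e-3)


def test_marginal_difference_parameter_recovery():
    """Simulated shared OR 1.29 at baseline 0.45, n = 50,000: posterior
    median standardised difference within 0.02 of 0.064."""
    arms = [CONTROL, Arm("neutral", 0)]
    df = make_index_frame(
        np.random.default_rng(8), 50_000, p_control=0.45,
        arm_log_or={Arm("neutral", 0): np.log(1.29)}, arms=arms,
    )
    res = _fit(df, "shared", n_draws=6000)
    out = res.marginal_difference()
    assert out.loc["pooled", "median"] == pytest.approx(0.064, abs=0.02)


# -- engines ---------------------------------------------------------------

def test_laplace_and_mcmc_agree(small_trial_occasions):
    """Median per-arm ORs from the two engines agree within 3% relative."""
    model = OnTimeLogisticModel.from_dataframe(small_trial_occasions, structure="shared")
    rl = model.fit(engine="laplace", n_draws=10_000, seed=1)
    rm = model.fit(engine="mcmc", n_draws=10_000, seed=1)
    ml = rl.arm_summary()["median_or"].to_numpy()
    mm = rm.arm_summary()["median_or"].to_numpy()
    assert np.all(np.abs(ml / mm - 1) < 0.03)


def test_mcmc_reproducible(small_trial_occasions):
    model = OnTimeLogisticModel.from_dataframe(small_trial_occasions, structure="shared")
    r1 = model.fit(engine="mcmc", n_draws=500, seed=7, n_burn=100, thin=2)
    r2 = model.fit(engine="mcmc", n_draws=500, seed=7, n_burn=100, thin=2)
    np.testing.assert_array_equal(r1.draws_fixed, r2.draws_fixed)


def test_laplace_reproducible_and_draw_count(small_trial_occasions):
    model = OnTimeLogisticModel.from_dataframe(small_trial_occasions, structure="full")
    r1 = model.fit(engine="laplace", n_draws=1234, seed=9)
    r2 = model.fit(engine="laplace", n_draws=1234, seed=9)
    np.testing.assert_array_equal(r1.draws_fixed, r2.draws_fixed)
    assert r1.n_draws == 1234


def test_unknown_engine_rejected(small_trial_occasions):
    model = OnTimeLogisticModel.from_dataframe(small_trial_occasions, structure="shared")
    with pytest.raises(ValueError):
        model.fit(engine="variational")


# -- model nesting & heterogeneity ----------------------------------------

def test_interaction_posteriors_centred_at_zero_under_no_interaction_truth():
    """Data generated with additive framing+timing effects only: the full
    model's interaction posteriors centre near zero (n = 50,000)."""
    rng = np.random.default_rng(10)
    framing_eff = {"neutral": 0.0, "positive": 0.25, "risk": 0.15, "social": 0.2}
    timing_eff = {-14: 0.0, 0: 0.1, 7: 0.05}
    lor = {a: framing_eff[a.framing] + timing_eff[a.timing] for a in SMS_ARMS}
    df = make_index_frame(rng, 50_000, arm_log_or=lor)
    res = _fit(df, "full", n_draws=4000)
    fx = [n for n in res.param_names if n.startswith("fx[")]
    medians = res.params_frame()[fx].median()
    # per-cell sampling noise is ~0.065 on the log-OR scale at this size, so
    # individual medians scatter around zero; the collection must centre there
    assert medians.abs().mean() < 0.05
    assert medians.abs().max() < 0.15


def test_schedule_point_heterogeneity_fit_runs(small_trial_occasions):
    model = OnTimeLogisticModel.from_dataframe(
        small_trial_occasions, structure="shared",
        heterogeneity_by_schedule_point=True,
    )
    res = model.fit(engine="laplace", n_draws=1000, seed=2)
    assert any(n.startswith("sms[x") for n in res.param_names)


def test_all_occasions_unit_includes_parent_effects(small_trial_occasions):
    model = OnTimeLogisticModel.from_dataframe(
        small_trial_occasions, structure="shared", unit="all_occasions"
    )
    assert model.design.n_parents > 0
    res = model.fit(engine="laplace", n_draws=500, seed=3)
    assert res.sigma_parent is not None
    assert res.draws_parent is not None


def test_monotone_pr_gt_1_in_true_or():
    """Mean posterior Pr(OR>1) increases with the true shared OR."""
    means = []
    for j, or_true in enumerate((1.0, 1.25, 1.5)):
        prs = []
        for rep in range(40):
            rng = np.random.default_rng(1000 * j + rep)
            lor = {a: np.log(or_true) for a in SMS_ARMS}
            df = make_index_frame(rng, 2000, arm_log_or=lor)
            prs.append(_fit(df, "shared", n_draws=1500).pooled_pr_gt_1())
        means.append(np.mean(prs))
    assert means[0] < means[1] < means[2]


def test_coverage_of_shared_or_credible_interval():
    """95% CrI for the pooled OR covers the truth in 90-99% of 200
    replicates (n = 5,000 each, true OR 1.3)."""
    covered = 0
    n_rep = 200
    for rep in range(n_rep):
        rng = np.random.default_rng(rep)
        lor = {a: np.log(1.3) for a in SMS_ARMS}
        df = make_index_frame(rng, 5000, arm_log_or=lor)
        summ = _fit(df, "shared", n_draws=2000, seed=rep).arm_summary()
        covered += int(summ["cri_low"].iloc[0] <= 1.3 <= summ["cri_high"].iloc[0])
    assert 0.90 <= covered / n_rep <= 0.99
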