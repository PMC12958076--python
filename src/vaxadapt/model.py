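"""Bayesian factorial logistic models for on-time vaccination.

Five pre-specified model structures estimate the conditional odds of on-time
vaccination for the 12 reminder arms versus control, all adjusting for
infant age (schedule point), calendar epoch (4-week intervals, first-epoch
reference, sparse epochs pooled with neighbours) and source clinic (random
effect); all-occasion analyses add a parent random effect:

* ``full``         — framing + timing + framing-by-timing interaction
                     (the primary, arm-saturated structure);
* ``no_interaction`` — framing + timing main effects only;
* ``framing_only`` — framing effects only;
* ``timing_only``  — timing effects only;
* ``shared``       — a single pooled any-reminder effect.

The arm block uses the overparameterised factorial expansion (4 framing + 3
timing + 12 interaction indicator columns with control as reference) under
independent N(0, 1) priors, which is exchangeable across arms and
separation-robust.

Two posterior engines share one log-posterior: ``laplace`` (penalised
Newton mode + multivariate-normal draws, with the random-effect SDs set by
a closed-form empirical-Bayes update) for the thousands of fits inside
operating-characteristic simulation, and ``mcmc`` (affine-invariant
ensemble sampling of all parameters including the log-SDs) for one-shot
analyses.

Usage follows the Model/Results convention::

    model = OnTimeLogisticModel.from_dataframe(occasions, structure="full")
    res = model.fit(engine="laplace", n_draws=10_000, seed=1)
    print(res.summary())
    res.arm_summary()          # per-arm OR posterior + Pr(best)
    res.marginal_difference()  # standardised on-time proportion differences
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .arms import FRAMINGS, SMS_ARMS, TIMINGS
from .config import PriorSpec
from .schedule import (
    STATUS_NOT_ONTIME,
    STATUS_ONTIME,
    classify_endpoints,
)

STRUCTURES = ("full", "no_interaction", "framing_only", "timing_only", "shared")

_MIN_EPOCH_CELL = 10  # epochs thinner than this pool with their neighbour


class ConvergenceWarning(UserWarning):
    pass


class SeparationWarning(UserWarning):
    pass


def _pool_epochs(epochs: np.ndarray, min_cell: int = _MIN_EPOCH_CELL) -> np.ndarray:
    """Map raw epoch indices to pooled group labels: consecutive epochs are
    merged (from the latest backwards) until every group has >= min_cell rows.
    Returns per-row group labels (the smallest epoch in each group)."""
    uniq, counts = np.unique(epochs, return_counts=True)
    groups: List[List[int]] = []
    acc: List[int] = []
    acc_n = 0
    for e, c in zip(uniq[::-1], counts[::-1]):
        acc.append(int(e))
        acc_n += int(c)
        if acc_n >= min_cell:
            groups.append(acc)
            acc, acc_n = [], 0
    if acc:
        if groups:
            groups[-1].extend(acc)
        else:
            groups.append(acc)
    label_of = {}
    for g in groups:
        lab = min(g)
        for e in g:
            label_of[e] = lab
    return np.array([label_of[int(e)] for e in epochs])


@dataclass
class Design:
    """Assembled design for one fit: response, fixed-effect matrix with
    per-column prior SDs, random-effect indicator blocks, and the contrast
    matrices mapping coefficients to per-arm log odds ratios."""

    y: np.ndarray
    X: np.ndarray
    names: List[str]
    prior_sd: np.ndarray
    clinic_idx: np.ndarray
    n_clinics: int
    parent_idx: Optional[np.ndarray]
    n_parents: int
    arm_contrast: np.ndarray          # (n_sms_arms, k_fixed)
    arm_labels: List[str]
    pooled_contrast: Optional[np.ndarray]
    age_col_of_point: Dict[int, Optional[int]]
    epoch_col_of_group: Dict[int, Optional[int]]
    latest_epoch_group: int
    n_per_arm: pd.Series
    schedule_points: List[int]


def build_design(
    occasions: pd.DataFrame,
    structure: str = "full",
    unit: str = "index",
    priors: PriorSpec = PriorSpec(),
    heterogeneity_by_schedule_point: bool = False,
) -> Design:
    """Build the analysis design from occasion-level data.

    Rows with early-vaccination exclusion are removed; the index unit keeps
    exactly one row per parent (``is_index``). Encodings use control /
    first schedule point / first epoch as reference levels; epochs with
    fewer than 10 rows are pooled with neighbours.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    if unit not in ("index", "all_occasions"):
        raise ValueError(f"unknown unit {unit!r}")
    if heterogeneity_by_schedule_point and structure != "shared":
        raise ValueError("schedule-point heterogeneity requires the shared structure")

    occ = occasions.copy()
    if "endpoint_status" not in occ.columns:
        occ["endpoint_status"] = classify_endpoints(occ)
    occ = occ[occ["endpoint_status"].isin([STATUS_ONTIME, STATUS_NOT_ONTIME])]
    if unit == "index":
        occ = occ[occ["is_index"].astype(bool)]
    if len(occ) == 0:
        raise ValueError("no analysable occasions")
    if occ["arm_framing"].isna().any():
        raise ValueError("occasion with endpoint but no assigned arm")

    y = (occ["endpoint_status"] == STATUS_ONTIME).to_numpy(dtype=float)
    n = len(occ)

    framing = occ["arm_framing"].astype(str).to_numpy()
    timing = occ["arm_timing"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    is_sms = framing != "control"

    cols: List[np.ndarray] = [np.ones(n)]
    names: List[str] = ["intercept"]
    sds: List[float] = [priors.sd_intercept]

    def add(col, name, sd):
        cols.append(col.astype(float))
        names.append(name)
        sds.append(sd)

    arm_labels = [a.label for a in SMS_ARMS]
    points_present = sorted(int(s) for s in occ["schedule_point"].unique())

    if structure in ("full", "no_interaction", "framing_only"):
        for f in FRAMINGS:
            add(framing == f, f"framing[{f}]", priors.sd_effects)
    if structure in ("full", "no_interaction", "timing_only"):
        for t in TIMINGS:
            add(timing == t, f"timing[{t}]", priors.sd_effects)
    if structure == "full":
        for f in FRAMINGS:
            for t in TIMINGS:
                add((framing == f) & (timing == t), f"fx[{f}:{t}]", priors.sd_effects)
    if structure == "shared":
        if heterogeneity_by_schedule_point:
            for s in points_present:
                add(is_sms & (occ["schedule_point"].to_numpy() == s),
                    f"sms[x{s}m]", priors.sd_effects)
        else:
            add(is_sms, "sms", priors.sd_effects)

    # age (schedule point) adjustment, first present point as reference
    age_col_of_point: Dict[int, Optional[int]] = {points_present[0]: None}
    for s in points_present[1:]:
        age_col_of_point[s] = len(names)
        add(occ["schedule_point"].to_numpy() == s, f"age[{s}m]", priors.sd_covariates)

    # epoch adjustment, pooled, first group as reference
    groups = _pool_epochs(occ["epoch"].to_numpy())
    glabels = sorted(np.unique(groups).tolist())
    epoch_col_of_group: Dict[int, Optional[int]] = {glabels[0]: None}
    for g in glabels[1:]:
        epoch_col_of_group[g] = len(names)
        add(groups == g, f"epoch[{g}]", priors.sd_covariates)

    X = np.column_stack(cols)

    # arm contrasts: coefficient combination giving each arm's log OR vs control
    k = X.shape[1]
    C = np.zeros((len(SMS_ARMS), k))
    for i, a in enumerate(SMS_ARMS):
        for j, nm in enumerate(names):
            if nm == f"framing[{a.framing}]" or nm == f"timing[{a.timing}]" \
               or nm == f"fx[{a.framing}:{a.timing}]" or nm == "sms":
                C[i, j] = 1.0
    pooled = None
    if structure == "shared" and not heterogeneity_by_schedule_point:
        pooled = np.zeros(k)
        pooled[names.index("sms")] = 1.0

    clinic_codes, clinic_idx = np.unique(occ["clinic_id"].to_numpy(), return_inverse=True)
    parent_idx = None
    n_parents = 0
    if unit == "all_occasions":
        _, parent_idx = np.unique(occ["parent_id"].to_numpy(), return_inverse=True)
        n_parents = int(parent_idx.max()) + 1

    n_per_arm = pd.Series(
        {
            "control": int((~is_sms).sum()),
            **{
                a.label: int(((framing == a.framing) & (timing == a.timing)).sum())
                for a in SMS_ARMS
            },
        }
    )

    return Design(
        y=y, X=X, names=names, prior_sd=np.asarray(sds), clinic_idx=clinic_idx,
        n_clinics=len(clinic_codes), parent_idx=parent_idx, n_parents=n_parents,
        arm_contrast=C, arm_labels=arm_labels, pooled_contrast=pooled,
        age_col_of_point=age_col_of_point, epoch_col_of_group=epoch_col_of_group,
        latest_epoch_group=glabels[-1], n_per_arm=n_per_arm,
        schedule_points=points_present,
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class OnTimeLogisticModel:
    """Bayesian logistic model of on-time vaccination for a factorial
    reminder trial. Construct via :meth:`from_dataframe`."""

    def __init__(
        self,
        design: Design,
        structure: str = "full",
        unit: str = "index",
        priors: PriorSpec = PriorSpec(),
        heterogeneity_by_schedule_point: bool = False,
    ):
        self.design = design
        self.structure = structure
        self.unit = unit
        self.priors = priors
        self.heterogeneity = heterogeneity_by_schedule_point

    @classmethod
    def from_dataframe(
        cls,
        occasions: pd.DataFrame,
        structure: str = "full",
        unit: str = "index",
        priors: PriorSpec = PriorSpec(),
        heterogeneity_by_schedule_point: bool = False,
    ) -> "OnTimeLogisticModel":
        design = build_design(occasions, structure, unit, priors,
                              heterogeneity_by_schedule_point)
        return cls(design, structure, unit, priors, heterogeneity_by_schedule_point)

    # -- parameter bookkeeping -------------------------------------------
    @property
    def _k_fixed(self) -> int:
        return self.design.X.shape[1]

    def _blocks(self) -> Tuple[int, int, int]:
        d = self.design
        return self._k_fixed, d.n_clinics, d.n_parents

    def _full_matrix(self) -> np.ndarray:
        """Dense [X | Z_clinic | Z_parent] matrix."""
        d = self.design
        n = len(d.y)
        parts = [d.X]
        Zc = np.zeros((n, d.n_clinics))
        Zc[np.arange(n), d.clinic_idx] = 1.0
        parts.append(Zc)
        if d.parent_idx is not None:
            if d.n_parents > 4000:
                raise ValueError(
                    "all-occasion designs with >4000 parents exceed the dense "
                    "random-effect solver; subset or aggregate first"
                )
            Zp = np.zeros((n, d.n_parents))
            Zp[np.arange(n), d.parent_idx] = 1.0
            parts.append(Zp)
        return np.column_stack(parts)

    def _lambda(self, sigma_c: float, sigma_p: float) -> np.ndarray:
        kf, nc, npar = self._blocks()
        lam = np.concatenate([
            1.0 / self.design.prior_sd**2,
            np.full(nc, 1.0 / sigma_c**2),
            np.full(npar, 1.0 / sigma_p**2) if npar else np.zeros(0),
        ])
        return lam

    def _fit_laplace(self, n_draws: int, seed: Optional[int],
                     start: Optional[np.ndarray],
                     sigma_start: Optional[Tuple[float, float]] = None) -> "OnTimeResults":
        from scipy.linalg import cho_factor, cho_solve, solve_triangular

        d = self.design
        A = self._full_matrix()
        y = d.y
        kf, nc, npar = self._blocks()
        rng = np.random.default_rng(seed)

        # penalised Newton on the coefficients, with a closed-form
        # empirical-Bayes update of the random-effect SDs at each inner
        # convergence
        if sigma_start is not None:
            sigma_c, sigma_p = sigma_start
        else:
            sigma_c = 0.15 * self.priors.sd_clinic_scale
            sigma_p = 0.15 * self.priors.sd_parent_scale
        theta = (
            start.copy()
            if start is not None and len(start) == A.shape[1]
            else np.zeros(A.shape[1])
        )

        def objective(th, lam):
            eta = A @ th
            return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (lam * th**2).sum())

        converged = False
        cf = None
        lam = self._lambda(sigma_c, sigma_p)
        obj = objective(theta, lam)
        for _it in range(60):
            eta = A @ theta
            mu = expit(eta)
            g = A.T @ (y - mu) - lam * theta
            w = np.clip(mu * (1 - mu), 1e-10, None)
            H = (A * w[:, None]).T @ A
            H[np.diag_indices_from(H)] += lam
            cf = cho_factor(H, lower=True)
            step = cho_solve(cf, g)
            t = 1.0
            for _ls in range(25):
                cand = theta + t * step
                cobj = objective(cand, lam)
                if cobj >= obj - 1e-12:
                    break
                t *= 0.5
            theta = cand
            obj = cobj
            step_small = np.abs(t * step).max() < 2e-4
            if not step_small:
                continue

            # mode found under the current SDs: empirical-Bayes SD update
            # using E[u^2] = mode^2 + posterior variance from the factor
            Linv = solve_triangular(cf[0], np.eye(H.shape[0]), lower=True)
            var_diag = (Linv**2).sum(axis=0)
            new_c = _halfnormal_sd_update(
                theta[kf:kf + nc], var_diag[kf:kf + nc], self.priors.sd_clinic_scale
            )
            new_p = sigma_p
            if npar:
                new_p = _halfnormal_sd_update(
                    theta[kf + nc:], var_diag[kf + nc:], self.priors.sd_parent_scale
                )
            sd_small = abs(new_c - sigma_c) < 3e-3 and abs(new_p - sigma_p) < 3e-3
            sigma_c, sigma_p = new_c, new_p
            lam = self._lambda(sigma_c, sigma_p)
            obj = objective(theta, lam)
            if sd_small:
                converged = True
                break

        if not converged:
            warnings.warn("Laplace mode search did not fully converge", ConvergenceWarning)
        if np.abs(theta[:kf]).max() > 10:
            warnings.warn(
                "extreme coefficient at the mode; possible separation handled by priors",
                SeparationWarning,
            )

        # final Hessian at the mode under the final SDs
        eta = A @ theta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (A * w[:, None]).T @ A
        H[np.diag_indices_from(H)] += lam
        L = np.linalg.cholesky(H)
        z = rng.standard_normal((A.shape[1], n_draws))
        draws = (theta[:, None] + solve_triangular(L.T, z, lower=False)).T  # (n_draws, p)
        return OnTimeResults(
            model=self, draws_fixed=draws[:, :kf], draws_clinic=draws[:, kf:kf + nc],
            draws_parent=draws[:, kf + nc:] if npar else None,
            sigma_clinic=sigma_c, sigma_parent=sigma_p if npar else None,
            mode=theta, engine="laplace", converged=converged, seed=seed,
        )

    def _fit_mcmc(self, n_draws: int, seed: Optional[int],
                  n_burn: int, thin: int) -> "OnTimeResults":
        import emcee

        d = self.design
        A = self._full_matrix()
        kf, nc, npar = self._blocks()
        prior_sd = d.prior_sd
        y = d.y
        Ac, Ap = self.priors.sd_clinic_scale, self.priors.sd_parent_scale
        has_parent = npar > 0
        ndim = A.shape[1] + 1 + (1 if has_parent else 0)

        def log_prob(th):
            beta = th[:kf]
            u = th[kf:kf + nc]
            v = th[kf + nc:kf + nc + npar]
            phi_c = th[kf + nc + npar]
            lp = 0.0
            eta = A @ th[:kf + nc + npar]
            lp += float(y @ eta - np.logaddexp(0.0, eta).sum())
            lp += -0.5 * float(np.sum((beta / prior_sd) ** 2))
            sc = np.exp(phi_c)
            lp += -nc * phi_c - 0.5 * float(np.sum(u**2)) / sc**2
            lp += -0.5 * sc**2 / Ac**2 + phi_c  # half-Normal prior + log-jacobian
            if has_parent:
                phi_p = th[-1]
                sp = np.exp(phi_p)
                lp += -npar * phi_p - 0.5 * float(np.sum(v**2)) / sp**2
                lp += -0.5 * sp**2 / Ap**2 + phi_p
            if not np.isfinite(lp):
                return -np.inf
            return lp

        # initialise walkers around the Laplace mode
        lap = self._fit_laplace(n_draws=2, seed=seed, start=None)
        centre = np.concatenate([
            lap.mode, [np.log(lap.sigma_clinic)],
            [np.log(lap.sigma_parent)] if has_parent else [],
        ])
        nwalkers = max(2 * ndim + 2, 48)
        nwalkers += nwalkers % 2
        rng = np.random.RandomState(seed if seed is not None else 0)
        p0 = centre[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))

        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
        sampler._random = rng
        need_steps = n_burn + thin * int(np.ceil(n_draws / nwalkers))
        sampler.run_mcmc(p0, need_steps, progress=False)
        chain = sampler.get_chain(discard=n_burn, thin=thin, flat=True)
        draws = chain[:n_draws]
        acc = float(np.mean(sampler.acceptance_fraction))
        converged = 0.1 < acc < 0.7
        if not converged:
            warnings.warn(
                f"ensemble acceptance fraction {acc:.2f} outside [0.1, 0.7]",
                ConvergenceWarning,
            )
        sig_c = float(np.median(np.exp(draws[:, kf + nc + npar])))
        sig_p = float(np.median(np.exp(draws[:, -1]))) if has_parent else None
        return OnTimeResults(
            model=self, draws_fixed=draws[:, :kf], draws_clinic=draws[:, kf:kf + nc],
            draws_parent=draws[:, kf + nc:kf + nc + npar] if has_parent else None,
            sigma_clinic=sig_c, sigma_parent=sig_p,
            mode=lap.mode, engine="mcmc", converged=converged, seed=seed,
            acceptance_fraction=acc,
        )

    def fit(
        self,
        engine: str = "mcmc",
        n_draws: int = 10_000,
        seed: Optional[int] = None,
        start: Optional[np.ndarray] = None,
        sigma_start: Optional[Tuple[float, float]] = None,
        n_burn: int = 800,
        thin: int = 5,
    ) -> "OnTimeResults":
        """Draw from the joint posterior. ``engine`` is ``"mcmc"`` (ensemble
        sampler over all parameters including log random-effect SDs) or
        ``"laplace"`` (normal approximation at the penalised mode)."""
        if engine == "laplace":
            return self._fit_laplace(n_draws, seed, start, sigma_start)
        if engine == "mcmc":
            return self._fit_mcmc(n_draws, seed, n_burn, thin)
        raise ValueError(f"unknown engine {engine!r}")


def _inv_diag(H: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(H)
    Linv = np.linalg.solve(L, np.eye(H.shape[0]))
    return (Linv**2).sum(axis=0)


def _halfnormal_sd_update(u_mode: np.ndarray, u_var: np.ndarray, scale: float,
                          floor: float = 0.01) -> float:
    """Closed-form maximiser of the half-Normal(scale) posterior of an SD
    given E[sum u^2] from the current Laplace fit."""
    s_sum = float(np.sum(u_mode**2 + u_var))
    m = len(u_mode)
    if m == 0:
        return scale
    var = scale**2 * (-m + np.sqrt(m**2 + 4 * s_sum / scale**2)) / 2
    return max(float(np.sqrt(var)), floor)


# ---------------------------------------------------------------------------


@dataclass
class OnTimeResults:
    """Posterior draws plus the summaries the adaptive design consumes."""

    model: OnTimeLogisticModel
    draws_fixed: np.ndarray           # (n_draws, k_fixed)
    draws_clinic: np.ndarray
    draws_parent: Optional[np.ndarray]
    sigma_clinic: float
    sigma_parent: Optional[float]
    mode: np.ndarray
    engine: str
    converged: bool
    seed: Optional[int]
    acceptance_fraction: Optional[float] = None

    @property
    def n_draws(self) -> int:
        return self.draws_fixed.shape[0]

    @property
    def param_names(self) -> List[str]:
        return self.model.design.names

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws_fixed, columns=self.param_names)

    # -- per-arm odds ratios ---------------------------------------------
    def arm_logor_draws(self) -> pd.DataFrame:
        """Per-reminder-arm log-odds-ratio draws vs control, per the fitted
        structure (reduced structures give identical draws to arms sharing
        the relevant component)."""
        C = self.model.design.arm_contrast
        draws = self.draws_fixed @ C.T
        return pd.DataFrame(draws, columns=self.model.design.arm_labels)

    def pooled_logor_draws(self) -> np.ndarray:
        pooled = self.model.design.pooled_contrast
        if pooled is None:
            raise ValueError("pooled effect is only defined for the shared structure")
        return self.draws_fixed @ pooled

    def pooled_pr_gt_1(self) -> float:
        return float((self.pooled_logor_draws() > 0).mean())

    def arm_summary(self, active_arms: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Per-arm posterior summary: median OR, central 95% CrI, Pr(OR>1),
        Pr(best) among active reminder arms, log-odds-ratio variance, n."""
        logor = self.arm_logor_draws()
        labels = list(logor.columns)
        active = list(active_arms) if active_arms is not None else labels
        act = logor[active].to_numpy()
        best = np.zeros(len(labels))
        win = np.argmax(act, axis=1)
        # ties in degenerate draws split deterministically by argmax order
        counts = np.bincount(win, minlength=len(active))
        for j, lab in enumerate(active):
            best[labels.index(lab)] = counts[j] / act.shape[0]
        q = np.percentile(logor.to_numpy(), [2.5, 50.0, 97.5], axis=0)
        n = self.model.design.n_per_arm
        return pd.DataFrame(
            {
                "arm": labels,
                "median_or": np.exp(q[1]),
                "cri_low": np.exp(q[0]),
                "cri_high": np.exp(q[2]),
                "pr_gt_1": (logor.to_numpy() > 0).mean(axis=0),
                "pr_best": best,
                "var_logodds": logor.to_numpy().var(axis=0, ddof=1),
                "n": [int(n.get(l, 0)) for l in labels],
            }
        ).set_index("arm")

    # -- marginal standardisation ----------------------------------------
    def marginal_difference(self) -> pd.DataFrame:
        """Posterior of the standardised difference in on-time proportion,
        each reminder arm vs control, at the most recent calendar epoch and
        a typical clinic/parent (random effects zero), equal-weight averaged
        over schedule points. For the shared structure a ``pooled`` row is
        included."""
        d = self.model.design
        latest = d.epoch_col_of_group[d.latest_epoch_group]
        base = self.draws_fixed[:, 0].copy()  # intercept
        if latest is not None:
            base = base + self.draws_fixed[:, latest]
        # control standardised proportion, averaged over schedule points
        p_control = np.zeros(self.n_draws)
        etas = []
        for s in d.schedule_points:
            eta_s = base.copy()
            col = d.age_col_of_point[s]
            if col is not None:
                eta_s = eta_s + self.draws_fixed[:, col]
            etas.append(eta_s)
            p_control += expit(eta_s)
        p_control /= len(d.schedule_points)

        logor = self.arm_logor_draws()
        rows = {}
        for lab in logor.columns:
            lo = logor[lab].to_numpy()
            p_arm = np.mean([expit(e + lo) for e in etas], axis=0)
            rows[lab] = p_arm - p_control
        if d.pooled_contrast is not None:
            lo = self.pooled_logor_draws()
            rows["pooled"] = np.mean([expit(e + lo) for e in etas], axis=0) - p_control
        out = []
        for lab, diff in rows.items():
            q = np.percentile(diff, [2.5, 50.0, 97.5])
            out.append({"arm": lab, "median": q[1], "cri_low": q[0], "cri_high": q[2]})
        return pd.DataFrame(out).set_index("arm")

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Bayesian logistic model of on-time vaccination",
            "=" * 54,
            f"structure: {self.model.structure:<16} unit: {self.model.unit}",
            f"engine:    {self.engine:<16} draws: {self.n_draws}",
            f"rows: {len(d.y)}   clinics: {d.n_clinics}   converged: {self.converged}",
            f"sigma_clinic: {self.sigma_clinic:.3f}"
            + (f"   sigma_parent: {self.sigma_parent:.3f}" if self.sigma_parent else ""),
            "-" * 54,
            f"{'arm':<18}{'median OR':>10}{'95% CrI':>18}{'Pr(>1)':>8}",
        ]
        for arm, r in self.arm_summary().iterrows():
            lines.append(
                f"{arm:<18}{r.median_or:>10.2f}"
                f"{'(' + format(r.cri_low, '.2f') + ', ' + format(r.cri_high, '.2f') + ')':>18}"
                f"{r.pr_gt_1:>8.2f}"
            )
        if d.pooled_contrast is not None:
            lines.append(f"pooled Pr(OR>1): {self.pooled_pr_gt_1():.3f}")
        return "\n".join(lines)
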