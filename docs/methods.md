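# Methods

`vaxadapt` simulates and analyses a Bayesian adaptive factorial trial of SMS
vaccination reminders: 12 reminder arms (4 content framings × 3 send timings
relative to the due date) against a no-reminder control, with
response-adaptive randomisation (RAR) and a control-discontinuation
superiority rule driven by pre-scheduled interim analyses.

## Outcome model

The primary endpoint is *on-time vaccination*: receipt of a scheduled dose
within the closed window [−14, +28] days of its due date. Receipt more than
14 days early means no reminder could have acted, so such occasions are
excluded from analysis; an occasion with no receipt record and complete
28-day follow-up counts as not on time (there is no missing outcome state).
The primary unit of analysis is the parent's *index occasion* — their first
SMS-eligible scheduled occasion after randomisation, one per parent; the
secondary unit is all SMS-eligible occasions of all of the parent's
children.

Five pre-specified Bayesian logistic structures model the conditional odds
of on-time vaccination, every one adjusting for infant age (schedule point
∈ {2, 4, 6, 12, 18, 48} months; first level as reference), calendar epoch
(4-week intervals of the due date; first epoch as reference; epochs with
fewer than 10 rows pooled with their neighbour) and source clinic (Gaussian
random intercept); all-occasion analyses add a parent random intercept:

| structure       | arm block                                            |
|-----------------|------------------------------------------------------|
| `full`          | framing + timing + framing×timing (arm-saturated)    |
| `no_interaction`| framing + timing main effects                        |
| `framing_only`  | framing effects                                      |
| `timing_only`   | timing effects                                       |
| `shared`        | one pooled any-reminder effect                       |

The full model's arm block is encoded as the overparameterised factorial
expansion — 4 framing, 3 timing, and 12 framing×timing indicator columns
with control as the implicit reference. The likelihood identifies 12
degrees of freedom; independent N(0, 1) priors regularise the redundancy
and make the parameterisation exchangeable across arms, which matters
because Pr(best) and the RAR weights must not prefer any arm a priori.
An arm's log odds ratio versus control is the sum of its framing, timing
and interaction coefficients.

Priors (configurable via `PriorSpec`): N(0, 1) on arm-effect columns,
N(0, 2.5) on the intercept and the age/epoch adjustments, half-Normal(1) on
the random-effect SDs. These are weakly informative on the log-odds scale
and keep separated cells (e.g. an all-success arm early in a trial) finite.

### Posterior engines

Both engines target the same log-posterior.

* **`mcmc`** — affine-invariant ensemble sampling (emcee) over all
  parameters including the log random-effect SDs, initialised around the
  Laplace mode; 10,000 retained draws by default, thinned, with the
  acceptance fraction attached as a convergence diagnostic. Used for
  one-shot analyses.
* **`laplace`** — penalised Newton iteration for the joint mode of (fixed
  effects, random effects), with the random-effect SDs updated at each
  inner convergence by a closed-form empirical-Bayes step: the half-Normal
  MAP given E[u²] = û² + posterior variance from the current Hessian
  factor. Draws are taken from the multivariate normal at the mode
  (inverse-Hessian covariance). Uncertainty in the SDs themselves is not
  propagated; arm-level odds-ratio summaries — the quantities the adaptive
  rules consume — are insensitive to this, and a cross-engine test holds
  median ORs to within 3%. Used for the thousands of fits inside
  operating-characteristic simulation.

Numerical details: Newton steps use a Cholesky solve with backtracking line
search on the penalised log-likelihood; convergence demands a maximum step
below 2×10⁻⁴ on the log-odds scale and an SD change below 3×10⁻³; weights
are floored at 10⁻¹⁰; an SD floor of 0.01 prevents degenerate collapse. A
coefficient magnitude above 10 at the mode raises a separation warning; a
failed mode search raises a convergence warning and flags the result rather
than failing silently.

### Posterior summaries and marginal standardisation

Per arm: median OR, central 95% credible interval (2.5th/97.5th
percentiles), Pr(OR > 1), Pr(best) — the fraction of draws in which the
arm's conditional log-odds is maximal among *active reminder arms* (control
is excluded, matching its role in the RAR rule) — the variance of the
arm's log-OR draws, and the current sample size. Marginal standardised
differences are computed per draw as the difference in predicted on-time
proportion (arm minus control) at the most recent calendar epoch with
random effects set to zero ("typical" clinic/parent), averaged with equal
weights over schedule points.

## Randomisation

Mass-weighted urn design (MWUD): each arm holds mass m_k, initialised to
α·ρ_k (targets ρ, urn parameter α = 4 by default). A fresh parent draws arm
k with probability ∝ max(m_k, 0); then m_k ← m_k − 1 and every active arm
is replenished by its target, conserving total mass α. This tracks targets
with bounded imbalance (empirically |n_k − nρ_k| ≤ α + 1). A parent seen
before — any sibling of an enrolled child — always receives the logged
arm with no urn update. Initial targets: 1/5 control and 1/15 per reminder
arm, giving margins of 1/5 per framing and 4/15 per timing. Retargeting
resets masses to α times the new targets (carrying residual masses across a
sharp target change can strand negative mass); a deactivated arm's target
is zero forever.

## Adaptation and stopping

Interim analyses fire when 1,500 index occasions have completed follow-up,
then after every additional 500 (≈100 expected per reminder arm at first
look). At each interim the full and shared models are refitted to the data
frozen at the trigger date. The RAR weight for reminder arm a is

    w_a = sqrt( Pr(best)_a · Var(log-odds)_a / n_a ),

normalised to mass 4/5 while control is active (control fixed at 1/5) and
to 1 afterwards. The square root spans the whole product — the
variance-stabilised reading of the rule; the sqrt-of-Pr(best)-only variant
sits behind `sqrt_of_product=False`. Effectiveness is declared, and control
allocation permanently dropped, when the shared model's pooled Pr(OR > 1)
or any single arm's Pr(OR > 1) from the full model reaches the superiority
threshold. Control outcomes remain in every later analysis dataset; only
future allocation stops.

The threshold itself is calibrated under the global null. Because the only
threshold-driven action is the declaration, a trial's pre-declaration
trajectory is identical at every threshold; one batch of null replicates
run with an unreachable threshold therefore yields each replicate's running
maximum decision statistic, from which the null declare rate at *every*
candidate threshold follows exactly. The calibration routine returns the
smallest grid threshold whose null rate is ≤ 0.05 (default grid 0.95 …
0.9999) and fails explicitly if none qualifies. With 4,000 posterior draws
per interim fit the decision statistic has granularity 1/4000, so
thresholds beyond 0.99975 are unreachable by construction; the grid stays
below that resolution except for its top guard point.

## Synthetic populations

The generator emulates the statistical structure the analysis assumes, not
any real registry. Defaults (all configurable in `ScenarioConfig`):

* **Enrolment**: homogeneous Poisson arrivals, 50 parents/day, capped at
  10,000 parents; horizon 420 days. Clinic-onboarding waves are not
  modelled.
* **Families**: 20 clinics with Dirichlet size weights; parents carry 1–4
  children with probabilities (0.8565, 0.1328, 0.0100, 0.0007).
* **Occasions**: each child enters screening at a schedule point drawn from
  a configurable distribution (default weighted toward 2 months), first due
  date within 28 days of arrival, later occasions at the schedule-point age
  gaps while inside the horizon.
* **Outcome**: conditional on not-early, on-time is Bernoulli with
  logit⁻¹(logit(baseline_s) + arm log-OR + clinic effect [+ parent effect]
  + drift·epoch). Baseline on-time is flat 0.45 at every schedule point in
  the default evaluation scenario; a shaped example profile (peak at 4
  months, decline to 48 months) is provided for realism studies. Clinic SD
  0.15, parent SD 0.30, calendar drift −0.02 log-odds per 4-week epoch.
* **Early vaccination**: per-schedule-point probability of receipt earlier
  than −14 days, 0.20 at 2 months and 0.001 elsewhere, concentrating ~96%
  of early receipts at the 2-month point.
* **Receipt days**: on-time receipts fall piecewise-uniformly in the bins
  (−14, 0], (0, 7], (7, 28] with masses 31/118/137 of 286 (the only printed
  timing breakdown for a control arm); late receipts are 28 + Geometric(0.05)
  days; half of failures have no receipt record at all.

What the generator does *not* reproduce: real family/clinic clustering
beyond exchangeable random intercepts, seasonal (non-linear) calendar
effects, clinic outages, opt-outs after enrolment, or between-arm
differences in early vaccination. Passing tests demonstrate that the
machinery implements the design correctly under its assumed data-generating
process — not that the design behaves identically on any real population.

## Operating characteristics

`estimate_oc` runs independently seeded replicate trials (Laplace engine,
4,000 draws per fit) and reports the declare rate with its Monte-Carlo SE,
mean total sample size, and per-arm allocation means and quantiles. The
shipped evaluation uses 200 replicates per scenario and the 10,000-parent
cap — about 16 interim looks per null trial — which resolves a declare
rate of 0.05 to ±0.015 (1 MCSE) and keeps a full power-plus-null evaluation
within desk-scale minutes. Power replicates stop at first declaration
(later interims cannot change the cumulative declare indicator).

## Known limitations

* The Laplace engine's plug-in treatment of random-effect SDs understates
  their uncertainty; with 20 clinics the SD itself is weakly identified and
  its point estimate can sit well below the generating value without
  affecting arm contrasts.
* All-occasion (parent random effect) models use dense indicator blocks and
  are limited to a few thousand parents; the primary index-occasion
  analyses are unaffected.
* The MWUD urn is updated per arrival; the real-world batched-list variant
  is equivalent in distribution but not replicated operationally.
* Decision-statistic granularity is tied to the number of posterior draws;
  thresholds must stay below 1 − 1/n_draws to be reachable.
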