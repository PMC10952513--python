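# Methods

`duocomb` implements a two-stage Bayesian adaptive design for finding a
safe and efficacious dose combination of two agents given at continuous
dose levels, of the kind used for cytotoxic doublets such as
cisplatin/cabazitaxel. Stage I estimates the maximum-tolerated-dose (MTD)
curve under escalation with overdose control (EWOC); stage II, typically
run in a new but related patient population, searches that curve for the
most efficacious combination, borrowing stage-I efficacy data through a
robust exchangeable/nonexchangeable (EXNEX) hierarchy. This note records
the models, the algorithmic choices, the numerical decisions, and what the
test suite does and does not establish.

## Dose standardization and the MTD curve

Raw doses are mapped linearly onto [0, 1]; `(0, 0)` is the lowest
combination available in the trial, not "no drug". The marginal
dose-toxicity model is a logistic regression with nonnegative interaction,

    pi_T(x, y) = F(alpha0 + alpha1 x + alpha2 y + alpha3 x y),
    alpha1, alpha2 > 0, alpha3 >= 0,

reparameterized through the DLT probabilities rho00, rho10, rho01 at the
corners (0,0), (1,0), (0,1), which clinicians can elicit directly. For
fixed parameters the MTD set at target DLT rate `theta_T` is

    y(x) = (F^-1(theta_T) - F^-1(rho00) - alpha1 x) / (alpha2 + alpha3 x).

Because `y(x)` is strictly decreasing wherever toxicity is increasing in
each agent, its intersection with the unit square is a single closed
x-interval whose endpoints have closed forms; no root finding is needed.
"Equally spaced along the curve" is implemented as equal **arc length**
(the curve is the one-dimensional set of tolerable combinations, and arc
length does not privilege either agent's axis); equal-x spacing is
available as a config option. Arc length uses a trapezoid rule on a
2049-point grid (1e-6 agreement with adaptive quadrature is test-enforced).
Conditional-MTD solutions falling outside [0, 1] are truncated to the
nearest bound before dose assignment and the truncation is counted in the
trial log.

## Toxicity priors and inference

Informative priors anchor the model on a previously reported single MTD at
the standardized combination (1/3, 1/2): `rho01, rho10 ~ Beta(1.4, 5.6)`,
`rho00 / min(rho01, rho10) ~ Beta(0.8, 7.2)` conditional on the corners,
and `alpha3 ~ Gamma(shape 0.8, rate 0.0384)`. The posterior is sampled on
the unconstrained scale (logit of the ratio, logits of the corner
probabilities, log interaction) with an affine-invariant ensemble sampler
(emcee, stretch moves, vectorized log-density, walkers initialized from the
prior). Defaults for a single analysis are 24 walkers, 1500 steps with the
first half discarded; inside large simulations a lighter preset is used
(20 walkers x 400 steps). Split-Rhat across walkers and a batch-means ESS
are computed when diagnostics are enabled; non-convergence flags the result
rather than raising.

A 3-D midpoint-grid plus Gauss-Legendre quadrature oracle (over the ratio,
the two corner probabilities and the interaction) verifies posterior means
to 0.01 on small datasets.

## EWOC escalation (stage I)

Cohorts of two. Cohort 1 receives the fixed start combination
(0.33, 0.5). From cohort 2 on, one patient keeps the previous dose of one
agent and receives the feasibility-bound `alpha`-th percentile of the
posterior conditional MTD of the other agent; the conditioning pattern
alternates with cohort parity. The feasibility bound follows
`alpha = min(0.25 + 0.05 (c - 2), 0.5)` from cohort 2 onward — the
escalation cadence is per cohort, which matches the sequential refitting
and is configurable. The percentile is the inverted-CDF order statistic of
the per-draw conditional MTD, truncated to [0, 1].

After every cohort the trial stops if
`P(rho00 > theta_T + 0.1 | data) > 0.5` (the lowest combination is already
too toxic). The 0.1 margin is a named config field.

## Efficacy model and robust borrowing (stage II)

Each stage S has its own monotone logistic response surface

    pi_E^S(x, y) = F(beta0_S + exp(beta1_S) x + exp(beta2_S) y + beta3_S x y),

with `beta3_S >= 0` (synergy) and the exponentials enforcing monotonicity.
Only the main-effect pair `Psi_S = (beta1_S, beta2_S)` is shared across
stages, via a meta-analytic-combined hierarchy:
`Psi_1 ~ BVN(mu, Phi)` always, and

    Psi_2 ~ BVN(mu, Phi)   with probability omega,
    Psi_2 ~ BVN(0, R0)     with probability 1 - omega,

where `Phi` has SDs `tau1, tau2 ~ half-normal(0.5)` and correlation
`xi ~ U(0, 0.5)`, and `R0` has marginal SD 10 and correlation
`zeta ~ U(0, 0.5)`. Intercepts are `N(-1.8, 3.16^2)`, interactions
`Gamma(0.1, 0.1)`, and `mu ~ N(0, 3.16^2)` componentwise. `3.16` is a
standard deviation (variance about 10). The product `100 * zeta` is read
as the covariance of the nonexchangeable prior, i.e. `zeta` is its
correlation — consistent with its U(0, 0.5) support.

The binary exchangeability indicator is marginalized out (log-sum-exp of
the two branch densities weighted by `omega`), avoiding trans-dimensional
sampling; the posterior exchangeability weight is the average of per-draw
branch responsibilities. With no stage-2 efficacy data the weight reverts
to `omega` (test-enforced within MC error). `zeta` is sampled even when
`omega = 1`, where it is posterior-inert by construction. `tau` draws are
floored at 1e-6 to keep `Phi` invertible.

The 14-dimensional joint posterior mixes slowly under plain stretch moves,
so the efficacy fit initializes two thirds of the walkers around the
posterior mode (found by L-BFGS with a batched central-difference
gradient — one vectorized density call per gradient) and the rest
dispersed like the prior (keeping both EXNEX branches represented), and
samples with differential-evolution plus snooker moves. Individual
coefficients remain weakly identified by binary data — their posterior
means converge slowly — so tests compare bounded functionals (response
probabilities, exceedance probabilities) between routes instead of raw
coefficients wherever MC precision matters.

Stage-1 efficacy outcomes are generated at enrollment but enter the
likelihood only from the first stage-II analysis on, reflecting the three-
plus-cycle observability delay of the response endpoint.

## Stage II conduct, stopping, and the final test

The estimated MTD curve is built from the coordinatewise posterior medians
of the toxicity parameters at the end of stage I. If it misses the unit
square entirely the trial ends as "no tolerable dose set" (distinct from a
safety stop). A run-in of `n2` patients is allocated one each to `n2`
arc-length-equally-spaced curve points; thereafter `C2` cohorts of `m2`
patients are drawn by rejection sampling (uniform proposal, acceptance
ratio density over its maximum) from the normalized plug-in stage-2
efficacy density along the curve, with the MAC model refit after every
cohort. The plug-in uses posterior medians of the stage-2 parameters.

Stopping rules, both evaluated after the run-in fit and after every
subsequent cohort:

* **Futility** — stop when the maximum over the curve of
  `P(pi_E^2(x, y) > p0 | data)` is below `delta_0 = 0.1`. (The rule is the
  posterior exceedance probability compared to `delta_0`; this is the only
  reading consistent with the final test and `delta_0 < delta_u`.)
* **Safety** — with `k` DLTs among `n` patients pooled over both stages,
  stop when the Beta(0.5 + k, 0.5 + n - k) posterior probability that the
  DLT rate exceeds `theta_T + 0.1` is above `delta_theta2 = 0.9`
  (closed-form Beta survival). A config switch restricts the count to
  stage-II patients for sensitivity analyses.

At the planned end, exceedance probabilities are evaluated on a grid of
`grid_size = 101` arc-length-spaced curve points; the null "no tolerable
combination is efficacious" is rejected when the maximum exceeds
`delta_u = 0.4`, and the argmax point is recommended as the optimal
combination. Ties break toward the lowest dose of agent X (conservative
and deterministic). The feasibility-bound schedule continues unchanged
when an assignment is truncated at a dose bound.

Design defaults follow the motivating trial: `theta_T = 0.33`,
`p0 = 0.15`, `N1 = 30` (15 cohorts of 2), `N2 = 30` (run-in 10 plus 4
cohorts of 5).

## Synthetic scenarios

No external data are used anywhere. The packaged scenario configuration
provides two dose-toxicity truths whose MTD curves pass through the
standardized anchor (1/3, 1/2) — the interaction is solved exactly from
the anchor — and, per toxicity truth, two stage-II efficacy profiles whose
most efficacious combination sits at opposite ends of the curve.

Because the efficacy surface is monotone in each agent, a peak strictly
inside the curve can only arise from the composition `x -> pi_E(x, y(x))`
along the decreasing curve. The calibrator exploits this: for an interior
peak it bisects the X main effect until the composite argmax lands on the
target (raising a calibration error when the requested location is
unreachable — for steep shape controls the composite is convex and its
argmax jumps between the curve ends); for an endpoint peak it pins the
logit gap between the two curve ends (default contrast 1.5, putting the
opposite end near response probability 0.13 when the peak is 0.40). The
intercept then scales the peak to `p0 + 0.25 = 0.40` under H1 or `p0 =
0.15` under H0, within 0.005 on a 1001-point grid. Shape controls were
chosen so that roughly half of the curve lies above `p0` under H1 —
realistic humped profiles under which allocation quality and futility
stopping are genuinely informative metrics.

Stage-1 agreement variants: **CA** copies the stage-II parameters; **PA**
keeps the peak location (an intercept shift leaves the composite argmax
unchanged) but moves the peak response down by 0.15, operationalizing
"same optimal combination, different probabilities" with a maximum profile
difference of at least 0.05; **CD** recalibrates the peak at the opposite
end of the curve. Note that CD built this way conflicts with stage II
mostly through the intercept, which the hierarchy never borrows — two
profiles can disagree completely in shape while their main-effect pairs
remain compatible, so CD need not drive the posterior exchangeability
weight below the prior. Borrowing-direction tests therefore use truths
that conflict in the main effects themselves (a rising-in-x against a
falling-in-x profile).

DLT and response outcomes are independent Bernoulli draws from the true
surfaces; the toxicity truth is shared by both stages.

## Simulation engine and metrics

Replicate trials derive per-index seeds from the master seed via
`SeedSequence(master, spawn_key=(index,))`, so results are independent of
execution order and of the total replicate count, and two runs with equal
seeds are bitwise identical (test-enforced). Reported metrics: rejection
rate (Bayesian power under H1, type-I error under H0; trials stopped early
for futility or safety count as non-rejections, since the final test never
fires — a "completers-only" variant is reported alongside), the proportion
of rejecting trials whose recommendation has true stage-II response above
`p0`, the pooled proportion of stage-II patients treated above `p0`,
futility/safety stopping rates, mean DLT rates overall and within stage
II, the fraction of trials with DLT rate above `theta_T + 0.1`, and mean
sample size.

## Problem sizes used by the test suite

The acceptance-style checks run at deliberately reduced scale: J = 20
replicate trials per configuration (four configurations: H1/H0 crossed
with omega 0/0.25) under a light MCMC preset, with a two-standard-error
Monte-Carlo allowance added to each literature bound; the borrowing checks
use 60-400 efficacy observations per stage; oracle comparisons use
datasets of at most six patients where quadrature is exact. At J = 20 a
probe run gave power 0.85, type-I error 0.05, futility stopping 0.05 (H1)
and 0.65 (H0), correct recommendation 0.88, and stage-II allocation above
p0 of 0.67 — all inside the ranges reported for this class of design.
Production use at J = 1000 reproduces the same machinery with tighter MC
error and is a matter of wall-clock time (roughly 5-6 s per trial at the
simulation preset on one core).

## Known limitations

* The simulator emulates idealized conduct: instant DLT observation,
  efficacy revealed exactly at the stage-II analyses, no accrual gaps,
  dropouts or missingness; passing tests say nothing about those
  operational complications.
* Toxicity and efficacy are conditionally independent given dose; copula
  or latent-variable dependence is out of scope.
* Toxicity data are not borrowed across stages (the dose-toxicity profile
  is assumed common), and toxicity attributions are ignored.
* Efficacy monotonicity is assumed in each agent — appropriate for
  cytotoxics, not for molecularly targeted agents.
* The prior-predictive DLT probability at the anchor combination under the
  stated priors evaluates to about 0.53, not the nominal 0.33 the priors
  are described as implying; the interaction prior (mean about 21)
  dominates the predictive at interior doses. The priors are implemented
  exactly as specified; `scripts/acceptance.py` reports the honestly
  computed value.
* Ensemble MCMC on the 14-d hierarchy leaves individual coefficients with
  sizeable MC error at simulation presets; decision quantities
  (exceedance probabilities, medians of bounded transforms) are the
  reliable outputs.
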