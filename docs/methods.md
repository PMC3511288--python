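# Methods

This note documents the models, numerical choices and limitations of
`dcemix` in the way a maintainer or reviewer would want them stated.

## Choice model

Utility is linear and additive in the attribute levels (no effects coding,
no non-linearities): `U_isj = α·1[j=A] + β_i'x_isj + γ'(c_i⊗x_isj) + ε_isj`
with i.i.d. type-I extreme-value ε, so a task's choice is binary logit in
the attribute differences. The alternative-specific constant attaches to
the left-hand option (position bias). "Panel" means a single β_i draw
governs all of a respondent's tasks; the respondent-level likelihood is
therefore an integral over the mixing distribution of a product of
task-level probabilities.

Mixing distributions per coefficient:

* **fixed** — degenerate at the mean (also used for all interaction terms);
* **normal(μ, σ)** — transform `μ + σ·Φ⁻¹(u)`;
* **constrained triangular(μ)** — `μ·T(u)` with T the inverse CDF of the
  symmetric triangular on [0, 2], mode 1. Support is [0, 2μ], the spread
  equals |μ|, and every draw has the sign of μ. One free parameter. This is
  the conventional way to keep a cost coefficient weakly negative without a
  log-normal's heavy tail.

## Maximum simulated likelihood

* **Draws.** Halton sequences by default: dimension d uses the d-th prime
  base (table of 25 primes), the first 10 points are discarded (burn-in
  against start-up correlation in higher bases), and the pooled sequence is
  cut into consecutive per-respondent blocks, so each respondent has a
  distinct low-discrepancy sub-sequence. Pseudo-random uniforms are
  available via `draw_type="pseudo_random"`. Draws are built once per fit
  and held fixed across optimizer iterations (the simulated likelihood is
  smooth in the parameters).
* **Objective.** The per-respondent log of the draw-averaged product of
  probabilities, computed with `log_expit` and `logsumexp` throughout; task
  probabilities are floored at 1e-300 in the log domain and floor hits are
  reported as a diagnostic (they indicate too few draws or exploding
  parameters, and are zero in all shipped analyses).
* **Gradients.** Analytic: per-respondent scores are the draw-weighted
  (softmax of the per-draw panel log-likelihood) sums of logit residuals
  times attribute differences, with the chain factors Φ⁻¹(u) for normal
  spreads and T(u) for triangular means. This makes a 14-parameter,
  n=1000, R=500 fit a ~1-minute job on one core.
* **Optimizer.** L-BFGS-B on the *per-respondent averaged* negative
  log-likelihood (so tolerances are sample-size invariant), gradient
  tolerance 1e-5, at most 500 iterations. The `converged` flag re-checks
  the gradient norm at the optimum rather than echoing the optimizer. The
  normal σ parameters are unconstrained during optimization (the likelihood
  is symmetric in their sign) and reported as magnitudes.
* **Standard errors.** Default: numerical Hessian of the simulated
  log-likelihood obtained by central differences of the analytic gradient;
  BHHH (outer product of scores) and the robust sandwich are options.
  p-values are two-sided asymptotic normal; no multiple-testing correction,
  matching standard choice-model reporting.
* **Starting values.** Zeros for means, 0.1 for spreads; any vector
  (e.g. a conditional-logit warm start) can be supplied.
* **Degenerate case.** With no random coefficients the same code path is an
  exact conditional logit (R collapses to 1); tests verify agreement with
  an independent implementation to ~1e-7.

By default the fit uses all ten tasks per respondent, including the repeat
and dominance tasks (each is a genuinely independent choice under the
model); a `roles` filter restricts to design tasks when preferred.

## Design engine

D-error is `det(I(β)⁻¹)^(1/K)` with I the MNL Fisher information summed
over design-role tasks; priors default to zero (utility-neutral design).
Duplicating every task exactly halves the D-error, relabelling alternatives
leaves it unchanged, and an attribute that never varies makes it singular —
all tested. The search initialises each factor with a shuffled,
level-balanced column over the 2·n_tasks alternative slots and proposes
swaps of two slots *within* one factor's column, accepting only strict
D-error improvements. Swaps preserve level balance exactly, and the
accept-if-better rule makes the final design never worse than its random
start. Blocking greedily assigns tasks to the emptiest block, breaking ties
by per-block level-count balance and then block index. Validity insertion
appends to each block one copy of a randomly chosen design task (optionally
with the alternatives reversed) and one dominance task built by setting
every directional attribute of one alternative to its preferred extreme
(with one attribute of the other side worsened if the template was already
best everywhere, keeping the dominance strict). Direction-less attributes
are held equal across the pair, since no dominance claim is possible for
them.

## Synthetic respondent generator

The generator exists because the original survey responses are not
deposited. It emulates the study's structure: 161 respondents randomly
assigned to 4 survey versions of 10 pairwise tasks over 8 linear
attributes; binary covariates drawn independently Bernoulli (private health
insurance 0.48, concession card 0.61, low income 0.37); individual
coefficients from the mixing distributions above; choices by the
Gumbel-difference construction (a uniform draw against the logistic
probability of alternative A — distributionally identical to adding
extreme-value noise to both utilities, with half the RNG calls). All
randomness flows from one `SeedSequence`, so identical seeds give
byte-identical datasets.

The preset coefficient values are **synthetic**: the study's fitted
coefficient table is in an unavailable supplement. They were chosen once to
reproduce its qualitative structure — death-risk reduction the most
important attribute by |β|×range, then current side-effect severity and
future side-effect risk; regimen the least important significant attribute
(−0.0937 per dose/day, back-derived from the published trade-off that a
4→1 doses/day switch is worth +0.2811 utility); cost constrained
triangular with a +0.004 cost×insurance deviation; symptom severity and
alcohol restrictions negligible; benefit attributes framed as reductions
(symptom frequency, chance of early death) so their coefficients are
positive — and the heterogeneity scale (σ = |μ| on the four health-outcome
factors) set so the emulated panel's dominance pass rate (~0.87), repeat
pass rate (~0.72) and κ (~0.45) sit near the published validity region.
The generator does **not** emulate behavioural artifacts (fatigue,
attribute non-attendance, left-right inattention beyond the constant),
correlated covariates, or correlated random coefficients, so passing tests
demonstrate statistical correctness of the machinery, not behavioural
realism of any particular dataset.

## Validity statistics

Monotonicity: pass iff the respondent chose the dominant alternative of
their block's dominance task. Repeat consistency: answers to the repeated
asking are mapped back to the original task's profile labels (both
same-order and reversed-order presentation are supported), pass iff the
same profile was chosen twice; κ uses the two-category Cohen formula
`(p_o−p_e)/(1−p_e)` on the pooled 2×2 first-vs-repeat table. When chance
agreement is degenerate (p_e = 1), κ is defined as 1 for perfect agreement
and NaN otherwise; the small-sample exact variant is not implemented. The
default analysis retains respondents who fail either test;
`refit_excluding` quantifies the effect of exclusion and refuses to run
below a configurable minimum sample (default 10).

## Post-estimation analytics

* **Null model** for fit statistics: the observed choice shares within the
  dataset (`LL₀ = Σ_alt n_alt·log(share_alt)`), not a forced 50/50. The LR
  degrees of freedom count the null as zero estimated parameters (the
  shares are treated as given, the NLOGIT convention); configurable.
* **Hit rate**: share of observations with predicted probability of the
  chosen alternative above 0.5; exact ties count one half so an
  uninformative model scores exactly 50%. Probabilities at the population
  means by default; per-respondent conditional coefficients are the
  alternative mode (the published description does not say which was used,
  so both are implemented).
* **Relative importance**: |β_f|×(level range of f), normalised to shares
  summing to 100%; scale-invariant by construction. Individual-level
  importance uses conditional coefficients.
* **Conditional individual coefficients**: simulation-based posterior
  means `E[β_i|y_i] = Σ_r β^(r)Π_tP_it(β^(r)) / Σ_rΠ_tP_it(β^(r))`,
  reusing the estimation draws — the standard mixed-logit construction for
  "individual beta estimates". They shrink toward the population mean as
  mixing variance vanishes.
* **Harm/benefit classification**: factors are tagged
  harm/benefit×immediate/long-term in a configuration dictionary (the
  preset tags the four health-outcome attributes); counts use strict
  inequality of summed importance shares.
* **Trade-offs**: ΔU = β_a·Δa; compensating move in b is −ΔU/β_b
  (marginal rate of substitution times the move), undefined at β_b = 0.

## Problem sizes and runtimes

The shipped analyses use the study scale (161 respondents, 10 tasks, 1000
Halton draws; ~15 s end to end) and a recovery exercise at 1000 respondents
with 500 draws (~1 minute). The test suite completes in about two minutes
on one core. Draw-count comparisons in tests average simulation error over
several parameter points because Halton convergence at a single point is
not monotone.

## Known limitations

* No correlated random coefficients, latent classes, WTP-space estimation
  or Bayesian estimation; alternatives are limited to labelled pairs
  without an opt-out.
* Simulated-likelihood estimates of mixing spreads carry a small downward
  finite-sample bias at panel lengths of ~10 tasks (visible as ~1–2 SE
  shrinkage of the largest spread in recovery exercises); it diminishes
  with more tasks per respondent, not with more draws.
* The design search is a local accept-if-better scheme; it guarantees
  improvement over its start, not global D-optimality.
* Bayesian-efficient designs over prior distributions are out of scope;
  priors enter the D-error as a point vector only.
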