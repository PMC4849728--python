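# Methods

## Model and assumptions

The package treats a two-alternative choice between a *risky* and an
*ambiguous* option as valuation of a latent variable `h` under a Bayesian
belief, followed by a softmax choice rule.

**Beliefs.** The risky option always carries a point-mass belief at a known
latent (`h* = 0.5` for the 50:50 urn; the half-width solving
`P_hit = target` for the fully visible target). The ambiguous urn carries a
Beta posterior `Beta(1 + n_red, 1 + n_blue)` under a flat `Beta(1, 1)`
prior — all compositions a priori equiprobable, inference with replacement
(Beta-Bernoulli). Sampling without replacement from the finite 100-ball urn
(beta-binomial inference) yields the same posterior mean under symmetric
evidence, which is why the probe-trial analyses are insensitive to the
sampling-scheme assumption; the equivalence is asserted in the tests. The
ambiguous motor target carries a uniform belief over the hidden half-width
on `[s, s + d]`, matching the generative design.

**Utilities.** `U(h) = Σ_o p(o|h) r(o)` with `r(failure) = −1`,
`r(success) = 0`, so `U ∈ [−1, 0]`: urn `U(h) = −(1 − h)`, motor
`U(h) = P_hit(h) − 1`. Rewards are fixed, not free parameters: risk
attitude via utility curvature is deliberately excluded so that `β` alone
carries the ambiguity attitude. The inverse-utility control condition is a
reward swap (`r(success) = −1`, `r(failure) = 0`).

**Valuation.** Expected utility `V₀ = E_q[U]`; free energy
`V_β = (1/β) log E_q[e^{βU}]`, equivalently the extremum of
`E_q̃[U] − (1/β) KL(q̃‖q)` attained at `q̃ ∝ q e^{βU}` (the variational
identity is verified numerically in the tests). The dynamic
Gilboa-Schmeidler alternative values the ambiguous urn at the
posterior-mean utility under a fitted, possibly asymmetric `Beta(a₀, b₀)`
prior; it is defined for urn-type beliefs only.

**Choice.** `p(x_risk) = σ(α (V(x_risk) − V(x_amb)) + logit p₀)` with a
uniform prior policy `p₀ = 1/2` by default. `α` is constrained nonnegative:
a negative precision is unidentifiable against swapping the option labels.

## Numerical choices

- **Quadrature.** All expectations over beliefs use fixed-order (64)
  Gaussian rules. Beta beliefs use Gauss-Jacobi with the Beta density as
  weight function (exact for polynomial integrands up to degree 127 and
  accurate for sharply concentrated posteriors such as 50 red/50 blue
  shown); uniform beliefs use Gauss-Legendre on the interval. The
  free-energy log-expectation is evaluated with log-sum-exp stabilization.
- **Small `β`.** For `|β| < 1e-6` the certainty equivalent switches to the
  second-order expansion `E[U] + (β/2) Var[U]`, avoiding 0/0 while keeping
  the truncation error below ~1e-13 for utilities bounded in `[−1, 0]`.
- **Design solvers.** The average-hit-probability equation is inverted by
  Brent bracketing to 1e-10 absolute tolerance; the full-occluder width
  `d_f` brackets by doubling. Infeasible geometry (occluder wider than
  `d_f`) raises an error naming the bound.
- **Optimization.** Per-subject MLE runs a coarse grid (α log-spaced over
  [0.1, 100], 8 points; β signed-log-spaced over [−50, 50], 9 points; GS
  priors log-spaced over [0.03, 31.6], 5 points each) followed by bounded
  derivative-free Powell refinement from the three best grid points, with
  objective tolerance 1e-8. The results record how many restarts agree
  within 1e-4 of the best optimum. Fixing `β = 0` in the free-energy family
  reproduces the expected-utility fit exactly (same objective, same path).
- **Likelihoods.** Choice probabilities enter the likelihood in the log
  domain (`log σ` via `logaddexp`), so no ad-hoc probability flooring is
  ever applied.
- **Degenerate inputs.** Zero-width occluders reduce the uniform belief to
  a point mass; `d → 0` continuity of the average hit probability is
  asserted at `d = 1e-6`. A rate vector identically 1/2 makes the Wilcoxon
  test degenerate and returns p = 1; a zero-variance trend table returns
  statistic 0, p = 1.

## Synthetic data: what it emulates and what it does not

The generator reproduces the experimental design: urn compositions uniform
over {0, 10, …, 100} red per 100 balls, displayed sample counts uniform
over {0, 2, 4, 10, 50, 100}, 50% symmetric probe trials (probe feedback
from a 50:50 urn); motor hitting probabilities uniform over
{0.3, …, 0.7} (probes fixed at 0.5), ambiguity indices uniform over
{0, 0.1, …, 1}, occluder width `d = a·d_f`, visible half-width solved so
every level shares the trial's expected hit probability, hidden half-width
uniform over the occluded range, Gaussian endpoints. Default cohorts mirror
the study groups: 16 subjects, 600 urn or 750 motor trials each,
`α ~ U[5, 30]`, `β ~ U[−6, 6]`, endpoint SD 1 cm.

Deliberately not emulated: the adaptive tracking of the half-width `s*`
over a running trial window (replaced by a fixed endpoint SD per subject,
since the analysis consumes only the resulting hit probabilities), endpoint
bias or motor learning drift, reaction/decision times, the two visual
display variants for missing urn information, and the physical force
payoff. Passing tests therefore demonstrate correctness of the inference
pipeline under the stated generative assumptions — not that human data obey
them.

## Design choices where the design was open

- The risky motor target is modeled with the same expected hitting
  probability as the ambiguous target on every trial; probe trials are the
  `P_hit = 0.5` subset.
- The urn prior is the continuous `Beta(1, 1)` over the ratio even though
  true compositions live on an 11-point grid; the continuous prior is the
  model's own assumption about the decision-maker, not about the generator.
- Two-sided tests throughout (binomial, Wilcoxon, trend); no
  multiple-testing correction across subjects, matching per-subject
  reporting. Wilcoxon zeros are dropped (the "wilcox" convention) and the
  exact null distribution is used for n ≤ 25 without ties.
- Trend-test scores are the information levels themselves (0, 0.02, 0.04,
  0.10, 0.50, 1 for urns; `1 − a` for motor), i.e. genuinely linear
  weights, not ranks.
- Pooled model comparison uses `k = (params/subject) × n_subjects` and
  `n = total trials` in the BIC, and df = n_subjects (one extra `β` per
  subject) in the pooled likelihood-ratio test; per-subject df = 1 tests
  are reported alongside.

## Problem sizes

Simulation-based checks run at the study's own scale where that is cheap
(16 subjects × 600 trials for recovery; 200 replicate subjects for
trend-test power; 10⁵ draws for Monte-Carlo hit rates; 10⁶ draws for the
valuation oracles). These sizes are the package's test conventions and are
stated in the relevant tests.

## Known limitations

- `β` is weakly identified from motor-task data alone: in the
  small-`|βU|` regime the choice logit depends on `α` and `β` mainly
  through their product times the belief variance, so the likelihood
  surface has a flat `α`-`β` ridge. Urn data (and the probe-information
  gradient) break the degeneracy; recovery guarantees in the tests are
  stated for urn cohorts.
- The free-energy and Gilboa-Schmeidler families mimic each other closely
  on this design at realistic trial counts; BIC selection between them is
  unreliable even on synthetic data generated from one of them (raw
  likelihood ordering is the sharper diagnostic).
- The fitting layer assumes trialwise independence of choices given
  parameters; sequential effects (learning, perseveration) are out of
  scope.
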