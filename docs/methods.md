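# Methods

This note documents the models, the synthetic data-generating process, the
estimation machinery, and the numerical and design choices behind
`itchoice`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Models and choice rules

Eleven models are implemented (see the README for the value functions).
Amounts are in currency units, delays in the design's native time unit
(days for the Kirby and tailored designs, months for the factorial grid).
Rate-like parameters (k, α, β, δ, λ, τ, γ) are therefore unit-dependent;
the package records the time unit on every item set and dataset and never
converts units silently.

Choice rules:

* The seven multiplicative discounted-utility models and the Additive
  Utility model use the logistic rule `p_LL = L[σ(V_LL − V_SS)]`, σ > 0.
  Larger σ means more deterministic choice.
* The Proportional Difference model uses a probit rule `p_LL = Φ[σ(d − δ)]`
  on the proportional-difference statistic
  `d = (max|x| − min|x|)/max|x| − (max|t| − min|t|)/max|t|`, parameterized
  so that larger σ likewise means more deterministic choice. When the SS
  option is immediate (`t_ss = 0`) the delay term equals 1 for every LL
  delay, so the model cannot express delay effects on such items — a
  structural property, not a bug.
* ITCH is a logistic regression on the absolute and relative amount and
  delay differences with the per-item attribute **means** as reference
  points (`x* = (x_ss + x_ll)/2`, `t* = (t_ss + t_ll)/2`).
* The Trade-off model compares `Q_v = v_LL − v_SS` (log-utility advantage)
  with `Q_w = (κ/α)·log[1 + α((w_LL − w_SS)/θ)^θ]`. Only the
  positive-payoff branch of the value function is implemented; no item in
  any supported design has negative payoffs.

### Parameter supports and transforms

Each parameter carries a support (positive; unit interval; θ ≥ 1;
unconstrained) and a matching transform to an unconstrained scale (log;
logit; log(θ−1); identity). Populations, priors and optimizers all operate
on the unconstrained scale, so draws respect supports by construction.
Two deliberate subtleties:

* **Double Exponential ordering.** The likelihood is symmetric under
  swapping (β, ω) with (δ, 1−ω). We break this label-switching by fixing
  β ≥ δ — β is the fast "impatient" rate, δ the slow "patient" one — via
  the joint transform `u = [log(β−δ), log δ, logit ω, log σ]`.
* **Boundary evaluation.** Supports are closed at their boundary for
  *evaluating* value functions (k = 0, ω = 1, β = δ are legitimate
  reduction limits); sampling and estimation work strictly in the open
  interior, which is all the transforms can reach.

### Numerical stability

`p_LL` in the forward direction is the plain logistic/probit value with no
clipping; at extreme utility differences it may round to 0.0 or 1.0 in
floating point. Likelihoods never use the forward probability: they use
`log_expit(±η)` and `log_ndtr(±η)`, which are finite for every finite
decision statistic η. The Trade-off rule is evaluated as
`L[(log Q_v − log Q_w)/ε]`, which is the printed ratio form rewritten to
avoid overflow for small ε. Non-finite intermediates raise an error naming
the offending term rather than propagating NaN.

## Choice-set designs

The 27 Kirby items are embedded verbatim from the canonical questionnaire
and re-validated against the instrument's published structure (ranges,
immediacy, 3 × 9 magnitude tiers) at every call.

The tailored design is a **surrogate** for the interactive adjustment procedures used in
tailored experiments, whose exact update rules are rarely published in
full. Given a generating model and parameter
vector, the structurally constrained attributes are drawn uniformly
(integer SS values in [2, 40]; LL amounts in [4, 80] for the delay
subsets), and the free attribute (SS amount for the two delay-effect
subsets, LL delay for the magnitude subset) is set to the generating
model's `p_LL = 0.5` indifference point — found by bisection on the choice
probability, which works uniformly for utility-based and attribute-wise
models — then multiplied by jitter uniform on [0.7, 1.3] and clipped to
keep the item a valid SS/LL pair (LL delays capped at 200 days). The
jitter keeps simulated choice rates near but not exactly at 50%,
reproducing the qualitative polarization such tailoring induces without
claiming to replicate the original staircase. Outputs are labelled as
surrogate-generated in run manifests.

## Synthetic populations

Participant-level parameters are drawn from independent normals on each
parameter's unconstrained scale. The defaults (in `POPULATION_DEFAULTS`)
are weakly informative choices made once, per model, to produce
non-degenerate choice behaviour on the supported designs — e.g. Hyperbolic
`log k ~ N(log 0.1, 1)`, `log σ ~ N(log 0.1, 1)` in design-native units.
Every default is overridable per parameter. The generator emulates the
long-format structure of real choice-experiment deposits (participant ×
item rows, binary choice, effect-subset labels) but **not** demographic
covariates, response times, item-order effects, or within-session
non-stationarity — so passing tests speak to estimation machinery under
the stated model, not to any of those real-data complications.

Seeding is a splitting ledger: a master seed spawns one substream per
participant, and per-stage children (simulation vs fitting) are spawned
from those, so any cell of a larger study regenerates bit-identically in
isolation.

## Estimation

Two modes behind one contract:

* **MAP + Laplace** (`mode="map"`): BFGS on the unconstrained negative log
  posterior (one jittered restart if the first attempt fails), a central
  finite-difference Hessian (regularized to positive definiteness if
  needed), and seeded draws from the resulting normal. Medians and
  credible intervals are percentile-based on the back-transformed draws,
  so monotone-transform parameters get asymmetric, support-respecting
  intervals. Deterministic given the seed and ~10 ms per two-parameter
  fit, which is what makes 10⁴-fit recovery studies tractable.
* **Ensemble MCMC** (`mode="mcmc"`): one independent emcee ensemble per
  chain, initialized from the prior; retained draws are the flattened
  post-warmup walker states trimmed to the configured count. Split-R̂ and
  bulk ESS (arviz) are computed per parameter; a fit is flagged
  non-converged when any R̂ > 1.01 or ESS < 400. Flagged fits are
  retained, surfaced in logs, and counted in recovery flag rates — never
  silently dropped, since dropping would bias recovery summaries.

The default sampler budget is 4 chains × 2000 warmup × 2000 retained
draws = 8000 retained samples. Priors default to the population
distributions widened ×2 in scale: proper, and weakly informative even for
27-item datasets.

The hierarchical model places participant vectors `u_j ~ N(μ, diag(s))` on
the unconstrained scale with hyperpriors `μ ~ N(prior loc, prior scale)`
and `log s ~ N(log 0.5, 1)`, sampled jointly by the same ensemble
machinery. The scale-to-zero funnel limits how sharply `s` can collapse at
small warmup budgets; the test suite uses long-warmup configurations on
thinned item sets to keep this check honest and fast.

WAIC is computed from the pointwise log-likelihood matrix as
`lppd_i = log mean_s exp(ll_si)`, `p_i = var_s(ll_si)` (ddof = 1),
`WAIC = −2 Σ_i (lppd_i − p_i)`, with the standard error
`√(n · var_i)` of the per-observation deviance contributions.

## Recovery and consistency analyses

A recovery cell simulates `n_combos × n_replicates` response sets (default
100 × 100 = 10 000 per model × design; 3 designs × 11 models = 330 000),
refits each independently, and summarizes per combination the mean of
per-replicate posterior medians and the averaged 95% CI (mean lower and
mean upper bounds). Generating combinations are sampled jointly — one
(participant, draw) row at a time — so parameter dependencies are
preserved; for tailored designs each combination's response sets use the
item set of the participant who supplied it.

Correlations between generating and recovered values are Pearson
correlations on the unconstrained scale (rate parameters span orders of
magnitude, so raw-scale correlations would be leverage-dominated; this is
configurable). The interval on a correlation is the 2.5/97.5 percentile of
one correlation per replicate index — a construction that uses only
quantities the pipeline already produces; users replicating published
interval conventions can substitute a model-based correlation.

The consistency analysis fits each participant's effect subsets
separately and correlates the per-subset estimates across participants.
With MCMC fits the 95% interval is draw-wise (correlate at each retained
draw index, take percentiles — a genuine credible interval); with MAP fits
it is a seeded bootstrap percentile interval around the point correlation.
Zero-variance estimate vectors yield an explicitly undefined (flagged)
correlation rather than NaN propagation. A correlation is "credible" when
its interval excludes zero.

## Problem sizes and scaled-down defaults

The full published-scale recovery grid (330 000 fits with NUTS-scale
budgets) is a cluster-sized computation. The package's tested
configuration exercises the identical pipeline at desk scale: 50
dispersed combinations × 1 replicate per model in MAP mode for the
factorial-design recovery (minimum generating–recovered correlation for
Exponential/Hyperbolic k and σ, reported by `scripts/acceptance.py`),
200 replicate fits for the interval-coverage check, and long-warmup
ensemble runs on thinned item sets for the hierarchical checks. These
sizes are the package's default experiment definitions; all counts are
parameters of `RecoveryPlan` and `SamplerConfig`.

## Known limitations

* The ensemble sampler is not gradient-based; at publication-scale budgets
  it needs more function evaluations than NUTS for the same effective
  sample size, and hierarchical scale parameters mix slowly in the funnel.
  The diagnostics contract makes this visible rather than hiding it.
* The Laplace approximation is asymptotic; for one-sidedly identified
  degenerate data (e.g. all-identical choices) its intervals are wide but
  their exact calibration is prior-dependent.
* The tailoring surrogate reproduces the structure and qualitative
  polarization of adaptive item generation, not the original staircase.
* Only positive payoffs are supported (no Trade-off loss branch); no
  response-time or evidence-accumulation modelling; no adaptive design
  optimization.
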