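# itchoice

Tools for studying how reliably the parameters of inter-temporal choice
models can be estimated. The package implements eleven prominent models of
choice between a smaller-sooner (SS) and a larger-later (LL) monetary
option as simulable, fittable likelihoods; the three classic choice-set
designs used to elicit such choices; individual and hierarchical Bayesian
estimation with WAIC model comparison; and the two reliability analyses
that motivate everything else — **parameter recovery** (simulate from known
values, refit, correlate) and **parameter consistency** (fit the same
person's different item subsets separately and correlate the estimates).

It is aimed at researchers in mathematical psychology and behavioural
economics who use discounting parameters as measurements — e.g. a discount
rate *k* as an index of impatience — and need to know whether a given
design can actually support that use.

## Models

Seven discounted-utility models value each option separately and choose by
a logistic rule on the utility difference, `p_LL = L[σ(V_LL − V_SS)]`:

| model | value function |
|---|---|
| Exponential | `V = x·exp(−kt)` |
| Hyperbolic | `V = x / (1 + kt)` |
| Double exponential | `V = x·[ω·exp(−βt) + (1−ω)·exp(−δt)]` |
| Generalized hyperbolic | `V = x / (1 + k·t^s)` |
| Hyperboloid | `V = x / (1 + kt)^s` |
| Generalized hyperbola | `V = x / (1 + αt)^(β/α)` |
| Constant sensitivity | `V = x·exp(−(αt)^β)` |

The Additive Utility model, `V = x^α − λ·t^β`, uses the same choice rule
but discounts additively, which lets it produce the magnitude effect.
Three attribute-wise models compare amounts and delays across options
directly: the Proportional Difference model (probit rule on the difference
of proportional attribute advantages against a threshold δ), the
inter-temporal choice heuristic ITCH (logistic regression on absolute and
relative amount/delay differences, mean reference points), and the
Trade-off model (log-utility advantage `Q_v` weighed against a weighted
log-delay advantage `Q_w`, with `p_LL = Q_v^{1/ε} / (Q_v^{1/ε} + Q_w^{1/ε})`).
All likelihoods are evaluated in numerically stable log space.

## Designs

* `kirby_mcq()` — the 27-item Kirby monetary choice questionnaire
  (immediate SS of $11–80 vs LL of $25–85 at 7–186 days, three magnitude
  tiers of nine items).
* `factorial_grid()` — 380 items: $100 now vs $X in D months, X ∈
  {120,…,500} by $20, D ∈ {2,…,38} by 2 months, every combination once.
* `tailored_design()` — per-participant 300-item sets in three 100-item
  effect subsets (delay duration: `t_ll = 2·t_ss`; common difference:
  `t_ll = t_ss + 30` days; magnitude: `x_ll = 2·x_ss`), with the free
  attribute placed near a generating model's indifference point (a
  documented surrogate for the original adaptive procedure).

## Worked example

Simulate one hyperbolic decision maker on the 380-item factorial design
and fit the model back:

```python
from itchoice import (ParameterVector, SamplerConfig, factorial_grid,
                      fit_individual, simulate_choices)

items = factorial_grid()                      # $100 now vs $X in D months
truth = ParameterVector("hyperbolic", {"k": 0.15, "sigma": 0.08})
choices = simulate_choices("hyperbolic", truth, items, seed=42)
print(f"simulated {choices.sum()} larger-later choices out of {len(items)}")

fit = fit_individual("hyperbolic", items, choices,
                     config=SamplerConfig(n_chains=1, n_warmup=500,
                                          n_draws=2000, seed=0),
                     mode="map")
med, ci = fit.median(), fit.interval(0.95)
for name in fit.param_names:
    print(f"{name:6s} median {med[name]:.3f}   95% CI "
          f"({ci[name][0]:.3f}, {ci[name][1]:.3f})")
```

Output:

```
simulated 139 larger-later choices out of 380
k      median 0.148   95% CI (0.139, 0.159)
sigma  median 0.090   95% CI (0.072, 0.113)
```

A monthly discount rate of 0.15 and a choice-consistency parameter of 0.08
are recovered with tight intervals containing the generating values — this
design identifies the two-parameter hyperbolic model well. Rerunning the
same exercise on the 27 Kirby items yields visibly wider intervals and
lower generating–recovered correlations: reliability is a property of the
design, not just the model.

The same workflow is available from the shell: `itchoice simulate | fit |
compare | recover | consistency` (see `itchoice --help`); every command
writes a JSON manifest with its seed and configuration hash so results can
be reproduced exactly.

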