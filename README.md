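# ordtreat

Endogenous treatment effects models with **ordered outcomes**, built for
the classic epidemiological question that motivated it: does smoking
affect body-weight status (underweight / normal / overweight / obese)
when smoking itself is driven by unobservables that also drive weight?

A naive ordered probit of BMI class on a smoking dummy answers the wrong
question when smoking is endogenous — people may smoke *because* of
weight concerns, and stress, risk attitudes or dieting behaviour move
both. `ordtreat` estimates the joint model

    T* = γ₀ + z'γ + v,      T = 1[T* > 0]          (smoking)
    Y* = x'β + δT + ε,      Y = j iff μ_{j−1} < Y* ≤ μ_j   (BMI class)

with (v, ε) bivariate standard normal, corr(v, ε) = ρ, identified by
exclusion restrictions (variables in z but not x — here education and
state-level smoking prevalence). It provides:

- the exact bivariate-normal-CDF likelihood (default) plus simulated /
  quadrature latent-factor versions as cross-checking routes, with
  analytic gradients and observed-information standard errors;
- the univariate ordered probit and binary probit comparators;
- the likelihood-ratio test of error independence (H₀: ρ = 0, χ²(1));
- marginal treatment effects on category probabilities at the margin of
  treatment indifference, with percentile-bootstrap intervals;
- survey recoding (WHO BMI classes, food-frequency dichotomization,
  dummy coding with fixed reference categories, listwise deletion) and
  Table-1-style descriptives (cross-tabs, Pearson χ², t-tests);
- a synthetic-data generator with known ground truth that emulates the
  study's covariate margins, gender-split instrument, and published
  coefficient values.

## Worked example

```python
import numpy as np
from ordtreat import (simulate_dataset, scenario_params, build_design,
                      fit_etop, fit_ordered_probit, fit_probit,
                      lr_test_independence)

ds, truth = simulate_dataset(10_000, scenario_params("paper"), seed=7)
d = build_design(ds)

naive = fit_ordered_probit(d.y, np.column_stack([d.X.to_numpy(), d.t]))
joint = fit_etop(d.y, d.t, d.X, d.Z)
lr = lr_test_independence(joint, fit_probit(d.t, d.Z), naive)
```

Running this (see `examples/endogeneity_bias.py`) prints:

```
true delta               : 1.155   true rho: -0.50
naive ordered probit     : 0.360   (attenuated)
joint model delta        : 1.057 (se 0.074)
joint model rho          : -0.449
LR test of independence  : chi2(1) = 65.2, p = 6.7e-16
```

The generator's truth has a positive smoking effect (δ = 1.155) and
negative error correlation (ρ = −0.5). The naive model, blind to the
correlation, reports 0.360 — badly attenuated; the joint model recovers
δ and ρ within sampling error, and the LR test firmly rejects
independence, i.e. the naive coefficient should not be trusted.

The other scripts in `examples/` show the descriptives
(`simulate_and_describe.py`), bootstrap marginal treatment effects
(`marginal_effects.py`, e.g. smoking raising the obese-class probability
by +0.11 [0.06, 0.15] at the margin on a small synthetic sample), and
the agreement of the three likelihood routes (`likelihood_routes.py`).

A thin CLI wraps the same pipeline:

```bash
ordtreat simulate --n 3471 --scenario paper --out data/
ordtreat describe data/paper.csv
ordtreat fit-etop data/paper.csv --lr-test --stratify male
ordtreat run-all data/paper.csv --out results/
```

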