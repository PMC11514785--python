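# swfe — fixed-effects analysis of stepped-wedge cluster randomized trials

`swfe` is a toolkit for designing, simulating and analysing
stepped-wedge cluster randomized trials (SW-CRTs) with **binary or
count outcomes** under the **fixed-effects generalized linear model**

```
logit(E[Y_ijk]) = δ·Z_ij + φ_j + α_i      (binary outcomes, log odds ratio δ)
log(E[Y_ijk])   = δ·Z_ij + φ_j + α_i      (count outcomes, log rate ratio δ)
```

for individual `k` in cluster `i` during period `j`, with intervention
indicator `Z_ij`, shared period effects `φ_j` (`φ_1 = 0` for
identifiability) and one fixed effect `α_i` per cluster.  Modelling
clusters as fixed effects absorbs all time-invariant cluster-level
confounding and keeps type-I error under control when the number of
clusters is small — a common situation in stepped-wedge trials.

The package is built around a question that matters in practice: **do
clusters that never receive the intervention (unexposed clusters)
contribute anything to a fixed-effects analysis?**  Trials can end with
unexposed clusters after early termination, or because a cluster was
added outside the randomization.  Since fixed-effects estimation is
often described as purely "within-unit" comparison, such clusters are
tempting to discard.  They should not be: the variance of the
intervention-effect estimator is the reciprocal of a Schur complement
of the Fisher information `X'VX`,

```
Var(δ̂) = (X'VX)⁻¹₍₁,₁₎ = (A − B'D⁻¹B)⁻¹ ,
```

and an unexposed cluster observed in two or more periods sharpens the
period-effect block `D`, which strictly decreases `Var(δ̂)`.  `swfe`
verifies this ordering numerically for any design, quantifies the gain,
and reproduces it in simulation.

## What's inside

| module           | purpose |
|------------------|---------|
| `swfe.design`    | build/validate wedge layouts (+ unexposed / always-exposed clusters), expand to individual-level model matrices, CSV round-trip |
| `swfe.glm`       | fixed-effects logistic & Poisson ML fitting (IRLS), Wald tests/CIs, AIC/BIC, period-homogeneity check |
| `swfe.variance`  | analytic `Var(δ̂)` via block decomposition and Schur complement; configuration-ordering and always-exposed-equivalence reports; precision-gain curves |
| `swfe.simulate`  | trial simulator (latent-normal cluster effects, gamma/Poisson cluster sizes), ICC ↔ τ² conversion, synthetic case-study fixture |
| `swfe.study`     | factorial simulation studies: bias, precision, power / type-I error, coverage, RMSE, Monte Carlo SE |
| `swfe.cli`       | `swfe simulate / run-grid / analyze / design-variance / make-fixture` |

## Worked example

Evaluate a 5-period trial with 4 stepped clusters plus one unexposed
cluster, binary outcomes with 30% baseline prevalence, odds ratio 1.25,
a linear secular trend of 0.1 per period, and 100 individuals per
cluster-period cell:

```python
import numpy as np
from swfe import (make_stepped_design, add_clusters, CellSizes, ordering_report)

design = add_clusters(make_stepped_design(4, 5), n_unexposed=1)
beta = np.concatenate([[np.log(1.25)],            # delta
                       0.1 * np.arange(1, 5),     # phi_2..phi_5
                       np.full(5, np.log(0.30/0.70))])  # alpha_1..alpha_5
rep = ordering_report(design, CellSizes.constant(design, 100), beta, "binary")
print(f"Var exposed_only      : {rep.var_exposed_only:.6f}")
print(f"Var plus_first_period : {rep.var_plus_first:.6f}")
print(f"Var full              : {rep.var_full:.6f}")
print(f"precision gain: {rep.var_exposed_only/rep.var_full:.3f}x")
```

prints

```
Var exposed_only      : 0.028861
Var plus_first_period : 0.028861
Var full              : 0.021811
precision gain: 1.323x
```

Reading: dropping the unexposed cluster (`exposed_only`) or keeping
only its first period (`plus_first_period`) give *identical* variances
— a single period contributes nothing to the period-effect contrasts.
Keeping all of its periods (`full`) cuts the variance of the
log-odds-ratio estimator by ~24%, i.e. a 1.32× precision gain, for
free.  The same machinery powers the `swfe design-variance` CLI
subcommand.

To analyse a dataset (here the bundled synthetic 5-cluster fixture):

```bash
swfe make-fixture --out trial.csv
swfe analyze trial.csv trial_design.csv --family binary
```

which reports `δ̂`, SE, 95% linear and odds-ratio CIs and AIC/BIC with
and without the unexposed cluster, the AIC/BIC check of common period
effects, and the analytic variance ordering at the fitted parameters.

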