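# clpnet

Cross-lagged panel network (CLPN) analysis of two-wave depressive-symptom
panels, with trajectory stratification, regularized network estimation,
expected-influence centrality, and bootstrap stability diagnostics.

## The problem

Longitudinal symptom-network psychometrics asks which depressive symptoms at
one time point *predict* which symptoms at a later time point. Given the nine
PHQ-9 items (scored 0–3) measured at two waves, a CLPN estimates, for each
wave-2 symptom *j*, the penalized regression

```
z(y_j^T2) = Σ_i  b_ij · z(y_i^T1)  +  γ' x  +  ε_j
```

with all nine standardized wave-1 items (and optional covariates *x*) as
predictors, coefficients regularized by the LASSO

```
min_β  (1/2n) Σ r²  +  λ Σ|β|
```

and λ chosen per equation by 10-fold cross-validation. The 9×9 matrix
`B = [b_ij]` is a directed network: diagonal entries are autoregressive paths
(a symptom predicting itself), off-diagonal entries are cross-lagged paths.
Sums of signed edges give the expected-influence centralities — out-EI(i) =
Σ_j b_ij (how much symptom *i* drives the next wave; high out-EI marks
candidate intervention targets) and in-EI(j) = Σ_i b_ij.

Before networks are fit, subjects are stratified into four depressive
trajectories by the PHQ-9 total cutoff (≥ 7 at a wave = probable
depression): **chronic** (depressed at both waves), **delayed** (only T2),
**recovery** (only T1), **resistance** (neither). One network is estimated
per trajectory group, then groups are compared by the Pearson correlation of
their vectorized edge matrices.

Accuracy and stability are quantified the way network toolkits do:
nonparametric bootstrap (subjects resampled with replacement, default 1000
iterations, full re-estimation each time) for 95% percentile CIs around
every edge; case-drop bootstrap for the correlation-stability (CS)
coefficient — the largest fraction of subjects that can be dropped while
the subsample centrality still correlates ≥ 0.7 with the full-sample
centrality with 95% confidence (CS ≥ 0.25 acceptable, ≥ 0.5 preferred);
and bootstrap difference tests for pairs of edges or centralities.

Because real cohort panels of this kind are typically not public, the
package ships a latent-Gaussian threshold simulator with known cross-lag
structure and four trajectory-scenario presets, so every stage is testable
against ground truth.

## Worked example

```python
import numpy as np
from clpnet import (make_scenarios, generate_panel, stratify_cohort,
                    fit_clpn, edge_summary, expected_influence)

spec = make_scenarios(n=2000, seed=13)["chronic"]
panel, truth = generate_panel(spec)

summary, _ = stratify_cohort(panel, cutoff=7)
print(summary.percentages)
# {'chronic': 88.4, 'delayed': 6.5, 'recovery': 1.6, 'resistance': 3.6}

fit = fit_clpn(panel, covariates=False, seed=13)
print(edge_summary(fit)["max_cross_lagged"])
# {'source': 'lack_of_energy', 'target': 'anhedonia', 'weight': 0.2767...}

table = expected_influence(fit, variant="overall").table
print(table.loc[table["out_ei_z"].idxmax(), "symptom"])
# suicidal_ideation
```

The scenario concentrates 88% of simulated subjects in the chronic
trajectory; the strongest recovered cross-lagged path is the
lack-of-energy → anhedonia edge the generator encodes, and suicidal
ideation — whose latent out-edges are the largest in the generator — tops
the out-EI ranking.

The numbered drivers under `analysis/` run the same steps as a narrative:
`01_simulate_cohort.py` draws a 4-scenario cohort, `02` stratifies it, `03`
fits the four group networks, `04` computes centralities and the 4×4
structure-correlation matrix, `05` runs the bootstrap and CS diagnostics.
Small tables land in `results/`; the large panel CSV goes to `scratch/`.

There is also a CLI: `clpnet simulate | stratify | fit | centrality |
compare | stability | run` (see `clpnet --help`).

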