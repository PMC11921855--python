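# Methods

## Model

For two waves of the nine PHQ-9 items, the cross-lagged panel network is
estimated equation by equation. For each target symptom *j*, the
z-standardized wave-2 score is regressed on all nine z-standardized wave-1
scores (and any standardized covariates) with the LASSO objective

    (1/2n) Σ_s (y_sj − x_s'β)²  +  λ_j Σ_k |β_k| .

The normalization matters: reported λ values are on the (1/2n)RSS scale
(the `glmnet`/scikit-learn convention). λ_j is chosen per equation as the
minimizer of 10-fold cross-validated squared error over a log-spaced grid
of 100 values from λ_max (the smallest penalty that zeroes every
coefficient) down to 10⁻⁴·λ_max; ties in CV error break toward the larger
λ, i.e. the sparser model. Folds come from a single seeded permutation per
equation, with the per-equation seed derived deterministically from the
master seed, so a fit is bit-reproducible from `(panel, seed)`.

Both outcomes and predictors are standardized within the analyzed group.
This is a documented modeling choice, not a data fact: it makes penalties
comparable across the nine equations and edge weights comparable across
groups of different variance, which the between-group comparisons assume.
The linear treatment of 0–3 ordinal items is the standard approximation in
this literature; the simulator is built around exactly that approximation
(see below).

Covariates are penalized together with symptom predictors — the default of
standard LASSO tooling — and never enter the edge matrix; their
coefficients are stored separately. Estimated edges are never thresholded;
the 0.025 cut used by the plotting helper is display-only.

A zero-variance outcome column cannot be standardized; that target's
incoming edges (column *j* of the matrix) are set to zero and the target is
flagged rather than failing the whole fit.

## Trajectory stratification

Subjects are dichotomized at each wave by the PHQ-9 total with an
*inclusive* cutoff (total ≥ 7 counts as probable depression — a score of
exactly 7 is depressed; this convention changes the classification of
boundary subjects and is therefore stated prominently). The 2×2 rule maps
(depressed at T1, depressed at T2) to chronic / delayed / recovery /
resistance. Reported percentages are rounded half-up to one decimal; raw
proportions are retained internally. Published tabulations of this design
are not always internally consistent (one source reports the chronic and
resistance shares as 15.1%/60.5% in its results but 11.6%/55.8% in its
discussion, and lists mutually inconsistent possible-edge denominators of
72/60/52/69 for a fixed 9-node network); the package reproduces the
results-section arithmetic and always reports cross-lags out of the 72
off-diagonal slots a 9-node directed network has.

## Centrality and comparison

out-EI(i) = Σ_j B[i,j], in-EI(j) = Σ_i B[i,j], in three variants: overall
(all paths), cross-lagged (each node's autoregressive path removed), and
cross-construct (paths within a community removed — identically zero when
all nine items form one community, so it is computed only on request).
Tables report raw and z-standardized values (sample sd, n−1); z-scoring
preserves rank order. The headline variant is overall with z values; the
cross-lagged variant is always written alongside since either convention is
defensible for a single-construct network.

Between-group comparison is the Pearson correlation of vectorized edge
matrices. Both conventions (81 entries with the autoregressive diagonal, 72
without) are computed, with-diagonal labeled as the default. The two-sided
p-value uses the t transform with n−2 degrees of freedom and is labeled
approximate: matrix entries are estimates from the same data, not
independent draws, and no exact reference distribution is attempted.

## Resampling

Bootstrap CIs are percentile intervals (2.5/97.5) from resampling subjects
with replacement and re-running the full estimation — including CV penalty
selection — per replicate (default 1000 iterations). Percentile rather than
BCa keeps replicate storage simple and matches common network-toolkit
defaults. A `fast` mode freezes each equation's penalty at its full-sample
value; it is used by the test suite and the scaled analysis drivers, where
re-running CV 10⁵ times would buy little: with n in the hundreds-to-
thousands and only nine candidate predictors, the selected λ is stable
across resamples.

The CS coefficient uses a fixed drop-proportion grid (0.10 to 0.70 in steps
of 0.05) with a fixed number of subsamples per level (default 100), a
transparent variant of the usual sampled-proportion procedure. For each
level, subsample centralities are Pearson-correlated with the full-sample
centrality; CS is the largest proportion whose empirical 5% quantile of
correlations is ≥ 0.7. The 0.7/95% convention underlies the usual reading
of CS (≥ 0.25 acceptable, ≥ 0.5 preferred). The number of replicates per
level and the grid are package decisions, not reported facts. A subsample
whose centrality vector is constant (correlation undefined) counts as
correlation 0 — the conservative direction.

Difference tests declare a pair of edges (or a pair of node centralities)
different when the 95% percentile interval of the replicate-wise difference
excludes zero. The decision is symmetric in its arguments and an item
compared with itself is never significant.

Every resampling routine spawns independent per-replicate substreams from
the master seed (`numpy` `SeedSequence`), so results do not depend on
execution order.

## Synthetic data

The generator draws wave-1 latent severities from a multivariate normal
with unit variances and equicorrelation 0.3 (a typical magnitude for
within-scale item correlations), applies the linear cross-lag model
`z2 = B'z1 + covariate effects + shift + N(0, 0.8²)`, and discretizes both
waves at thresholds (0.5, 1.2, 2.0), giving the right-skewed score
distributions community PHQ-9 samples show. The default B has
autoregression 0.3 on the diagonal and 12 cross-lags of magnitude 0.2–0.35,
with suicidal ideation broadcasting to several next-wave symptoms and lack
of energy driving anhedonia — the qualitative pattern the pipeline is
designed to detect. Spectral radius < 1 is enforced.

Scenario presets differ only in latent mean shifts (−0.45 low, +1.3 high,
with the wave-2 shift corrected for the carryover of the wave-1 mean
through B) chosen so each preset's cohort is ≥ 80% correctly labeled after
stratification; all four share one cross-lag support, so between-group
structure correlations on recovered fits are high by construction.

What the simulator does **not** emulate: item-level measurement
non-invariance, missingness, floor effects beyond thresholding, three-wave
dynamics, and — importantly — the attenuation-free world of continuous
data. Discretizing latents attenuates observed-scale coefficients toward
zero relative to B, so recovery is validated by correlation and sign
agreement with B, never by absolute equality. A further subtlety guides the
validation experiments: with correlated wave-1 latents, thresholding acts
like measurement error, so an edge that is zero on the latent scale can
have a genuinely nonzero observed-scale partial coefficient. Coverage
checks for "true-zero" edges therefore use independent wave-1 latents,
where the observed-scale truth really is zero. Passing tests demonstrate
that the estimation machinery recovers the structure its assumed model
generates — not that real panel data satisfy those assumptions.

## Numerical choices and degenerate inputs

- Coordinate-descent tolerance 1e-8 for single solves, 1e-6 inside CV
  paths; the solver is verified against a proximal-gradient oracle to 1e-6
  in objective value.
- λ = 0 falls back to least squares (the penalty-free limit).
- Constant predictor columns standardize to all-zero and are flagged; they
  yield exact-zero coefficients.
- z-standardizing a constant vector returns zeros plus a flag instead of
  dividing by zero.
- Groups smaller than a configurable minimum (default 50) are skipped by
  the pipeline with a warning rather than fit unstably.
- Cutoffs are restricted to [1, 27]; PHQ-9 totals outside [0, 27] are
  rejected.

## Problem sizes used by tests and drivers

Validation experiments use n = 1000–3000 subjects per cohort, 20 replicate
cohorts for recovery, 200 bootstrap iterations × 20 experiments for
coverage, and 100 case-drop replicates per grid level — sizes at which the
Monte-Carlo margins of the checked properties are comfortable. The analysis
drivers use 2000 subjects per scenario with 200 bootstrap iterations and 50
case-drop replicates per level in fast mode; library defaults (1000
iterations, full CV refits) remain available for production runs.

## Known limitations

- Ordinal items are modeled linearly; no ordinal-link or polychoric
  variant is provided.
- Two waves only; no random-intercept or multilevel CLPN.
- The structure-correlation p-value is approximate (see above).
- CS is reported on a fixed grid, so values are multiples of 0.05 and capped
  at 0.70.
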