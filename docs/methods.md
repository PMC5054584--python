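# Methods

This note records the models, numerical choices and known limitations of
the package, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and units

Beta values (`M/(M+U)`, the methylated fraction at a CpG) live in
probes × samples DataFrames with NaN as the explicit missing state; all
cross-matrix operations align by probe/sample identifier, never by
position, so cohorts with different probe orders cannot be silently
misaligned. Gestational age is decimal weeks everywhere internally. Blood
spots are collected up to weeks after birth while the methylome keeps
maturing, so the *effective* GA of a spot sample is
`clinical_ga_weeks + days_to_sampling/7` (integer days, converted at
ingest only); cord blood is sampled at birth and needs no correction.
Training responses and prediction accuracy both use effective GA.

## Quality control

Order is part of the contract: (1) any cell with detection p **strictly
above** 0.001 is set missing; (2) probes with missing fraction strictly
above 5 % are removed; (3) samples with missing fraction strictly above
5 % — recomputed on the probe-filtered matrix — are removed; (4) multiple
datasets are cut to their common probe set. Both 5 % thresholds and the
detection cut are read as strict inequalities (the natural reading of
"above 0.001" / ">5 %"); the filter order matters and is regression-tested
with a matrix where a probe's removal rescues a sample. Sex/age-discordance
pre-screening against an adult methylation clock requires that external
predictor and is out of scope; `filter_missingness` callers can drop an
exclusion list beforehand instead.

## Gold-standard BMIQ calibration

The original BMIQ reshapes type II probe distributions within one array.
The variant here serves between-sample calibration: the reference
distribution is the probe-wise mean over the pooled training samples
("gold standard"; pooled-sample mean rather than a mean of dataset means),
and each sample is transported onto it.

A three-component beta mixture (states U < H < M ordered by component
mean) is fitted by EM:

* initialization is deterministic — hard thresholds at β = 0.25 / 0.75
  with method-of-moments shape starts — so the fit is order-invariant and
  needs no random restarts;
* betas are clamped to [1e-6, 1−1e-6] before fitting (the beta likelihood
  is unbounded at 0/1);
* the M-step maximizes each component's weighted log-likelihood with a
  damped Newton iteration on (a, b), accepting an update only if it
  improves the expected complete-data log-likelihood; this generalized-EM
  step guarantees the observed log-likelihood is non-decreasing, which the
  tests assert directly;
* convergence: relative log-likelihood change < 1e-6, max 500 iterations;
  non-convergence returns the best fit flagged `converged=False` with a
  warning.

Transport: each sample value is assigned its maximum-posterior state
(ties go to the lower-mean state). U- and M-state values map through
beta-CDF quantile matching, `x' = F⁻¹_gold(F_sample(x))`. H-state values
map by the linear dilation that carries the sample's posterior
U/H and H/M crossing points onto the images of those points under the
U- and M-maps, which makes the transport continuous across state
boundaries and exactly the identity when a distribution is calibrated
against itself. All three maps are strictly increasing, so within-state
rank order is preserved; output is clipped to [0, 1]; missing cells pass
through untouched; a failed mixture fit falls back to identity with a
warning. Probe-type (I/II) chemistry is deliberately not modelled — the
calibration treats the whole array distribution.

**Caveat discovered during development and worth knowing about:** forcing
every sample onto the reference marginal couples probes through the
sample-level mixture fit. When a non-trivial fraction of probes shifts
with GA (50/2000 in the synthetic default — far more leverage per probe
than on a 450k array), the per-sample maps themselves become
GA-dependent and leak a small global GA-correlated shift into null
probes, badly inflating per-probe association tests. The pipeline
therefore feeds the EWAS and the cell deconvolution the QC'd + imputed
but *uncalibrated* matrix, and uses the calibrated matrix only for clock
training and prediction, where matching train/test distributions is the
point.

## kNN imputation

Missing values remaining after QC are filled probe-wise with k = 10
nearest neighbours. The distance between probes i and j is the Euclidean
distance over jointly observed samples, rescaled by the observed
fraction (`sqrt(Σ_joint d² · n/n_joint)`), so sparsely overlapping pairs
are not spuriously close; pairs with no joint observation are infinitely
far. Neighbours must be observed at the target sample; the imputed value
is the 1/(d+1e-6)-weighted mean; distance ties break on lexicographic
probe id, making the whole procedure deterministic. A probe with no
usable neighbour falls back to its own observed mean (warning); a fully
missing probe is an error (QC should have removed it). The
implementation is validated cell-for-cell against a naive O(p²) oracle.

## Elastic-net clock

glmnet parametrisation: objective
`(1/2n)‖y − b0 − Xb‖² + λ(α‖b‖₁ + (1−α)/2‖b‖₂²)`, α = 0.5 by default,
no covariates besides the CpGs. Predictors are standardized internally
for fitting and coefficients returned on the beta scale. The λ path has
100 log-spaced values from λ_max = max|X̃ᵀỹ|/(nα) (the smallest λ with an
all-zero solution) down to 1e-4·λ_max. λ is chosen by seeded ten-fold CV
(near-equal random folds, unstratified) at the minimum mean held-out MSE
— the minimum rule, not 1-SE. Within each fold the path is fitted with
warm starts from large to small λ (pathwise coordinate descent via
scikit-learn's solver); the CV bookkeeping is checked against a manual
fold-loop oracle at a tolerance where warm and cold starts coincide.
Models keep only nonzero coefficients; an all-zero solution raises with
advice to lower λ. At prediction time, clock probes absent from the data
are substituted with the gold-standard mean for that probe (warning);
more than 20 % missing clock probes is an error. Among highly correlated
CpGs the lasso component picks representatives somewhat arbitrarily, so
the *identity* of selected probes is less stable than the predictions —
only recall against planted causal sets is asserted, not exact selection.

## GA acceleration and associations

Acceleration is the residual of OLS `dnam_ga ~ 1 + clinical_ga` over the
pooled prediction set (cohort enters later models as a covariate, not the
residualization). Birthweight (grams) is regressed on acceleration +
clinical GA + race + cohort + cell proportions; birthweight percentile
omits clinical GA since the percentile is GA-standardized by
construction. Insurance (Medicaid vs private) is a logistic regression
on acceleration + clinical GA + race + cell proportions. Cell
proportions enter as all-but-one components because the simplex sum
makes the full set collinear with the intercept; constant and perfectly
collinear covariates are dropped with a warning. Complete separation in
the logistic model is flagged and refitted with a small L2 penalty so a
finite estimate is still reported (`flags=("separation_fallback",)`).

## Cell deconvolution

Reference profiles are mean betas of purified cell populations at
cell-discriminating probes: per type, probes ranked by the difference
between that type's mean and the mean of the others, top 50 per
direction by default, union over types. Proportions solve
`min ‖y − Rw‖²` subject to `w ≥ 0, Σw ≤ 1` (SLSQP with analytic
gradient, ftol 1e-14); the inequality constraint leaves room for cell
types missing from the reference panel, relevant in cord blood (e.g.
nucleated red blood cells when only a leukocyte panel is supplied). Real
450k reference panels are user-supplied inputs; the packaged profiles
come from the synthetic generator.

## EWAS

Per probe, OLS of beta on GA with cohort indicator covariates — a
fixed-effects meta-analysis "by indicator", exactly the pooled
formulation, not per-cohort inverse-variance pooling — optionally adding
cell proportions. The solve is vectorized over probes through one shared
hat matrix. Probes constant across samples are flagged degenerate
(slope 0, p = NaN) and excluded from significance counts. No multiple
testing correction by default (nominal p < 0.05 counts); Bonferroni and
BH-FDR columns are available. `compare_adjustment` pairs the t-statistics
of the adjusted and unadjusted runs and reports their correlation as the
robustness summary.

## Enrichment

BED semantics are 0-based half-open internally; probe positions (1-based)
convert at ingest. Shores are the ±1.5 kb island flanks minus islands;
shelves the next ±1.5 kb minus islands and shores; coordinates clip at 0;
the island > shore > shelf precedence defines a mutually exclusive
island-context label with "open_sea" as the remainder. Fisher tests are
two-sided by the standard exact definition (sum of all tables with
probability ≤ observed, fixed margins); the odds ratio is the sample OR
with a Haldane 0.5 correction only when a cell is zero, and defined as
1.0 when an entire margin is empty (no measurable association). SNP-in-
probe and race-associated-CpG enrichments reuse the same machinery with
user-supplied probe lists.

## Synthetic data generator

Per-sample betas are a cell mixture of simulated reference profiles
(Dirichlet proportions, concentration 10), plus linear GA effects on a
causal subset (slopes 0.005–0.03 β/week, random sign, anchored at the GA
midpoint), plus a per-probe-per-cohort batch shift (sd 0.01 beta), with
noise added on the logit scale (sd 0.3) and back-transformed — which
keeps betas in (0, 1) and mimics the variance shrinkage near the
boundaries seen on real arrays. GA is uniform on 24–44 weeks; one of
three cohorts is blood spots with integer sampling delays up to 39 days;
detection failures are planted at 0.5 %. Defaults were chosen once to
represent a multi-cohort neonatal study spanning extremely preterm
through post-term at desk scale (450 samples × 2000 probes).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: probe-type chemistry differences, spatial
chip artefacts, correlated CpG blocks (probes are conditionally
independent given cell mixture and GA), non-linear GA trajectories,
GA-correlated cell composition (cell mixture is independent of GA by
default, which is why the cell-adjusted and unadjusted EWAS agree so
closely here), and population structure in the covariates.

## Pipeline and reproducibility

`run_pipeline` chains mask → probe filter → sample filter → intersect →
gold standard → calibrate → impute → train → predict → deconvolution →
acceleration → EWAS, writing every artifact plus a deterministic
`summary.json`; any failure halts naming the stage, with prior artifacts
preserved. All randomness flows from one top-level seed expanded with
numpy `SeedSequence` spawning, so a rerun is byte-identical. Problem
sizes throughout the suite and the acceptance script (hundreds of
samples, thousands of probes) were chosen as the smallest scales at
which the statistical properties under test are stable.
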