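# Methods

This note records the modelling choices, defaults and numerical
conventions behind `connpred`, and what the synthetic validation does
and does not establish.

## Pipeline overview

Participant parcel time courses → per-participant Fisher-z Pearson
connectivity matrices → cohort feature matrix (vectorized upper
triangles, column-standardized) → per-parcel ridge regression with
randomized nested cross-validation → parcels × runs accuracy table →
pooled-Gaussian top-tail counts and a Gumbel block-maxima probability
index.

## Connectivity features

Time series are z-scored per parcel before Pearson correlation.
Correlations are clipped to |r| ≤ 1 − 1e−7 before the inverse
hyperbolic tangent so duplicated or degenerate series map to large but
finite z-values (atanh(1 − 1e−7) ≈ 8.4056) while preserving ordering;
the diagonal is set to 0 by convention. Upper-triangle columns are
ordered row-major — (1,2), (1,3), …, (P−1,P) — a fixed convention with
no statistical content. Column standardization uses the sample SD
(N − 1); zero-variance columns are zeroed with a warning rather than
dropped, so column indexing stays aligned with parcel pairs.

Standardization is computed once on the full cohort before
cross-validation (`standardize_mode="cohort-once"`, the default
analysis convention here). This leaks scale information across folds;
a leakage-free `"fold-wise"` option recomputes column statistics on
each outer training set and is logged when used.

## Ridge with randomized nested cross-validation

Estimator: β̂ = (XᵀX + λI)⁻¹ Xᵀ(y − c), prediction Xβ̂ + c. In the
default cohort-once mode the intercept c is the cohort outcome mean,
fixed once — the same convention as the feature standardization. The
alternative (re-centering y on each outer training fold) makes
maximally-shrunk predictions collapse onto fold training means, which
are mechanically anti-correlated with the held-out values and push
null-data accuracies to ≈ −0.2; fixing c once removes that artifact
while changing nothing else about the fit. Fold-wise mode centers on
the training fold, accepting the artifact in exchange for strict
out-of-sample hygiene.

Cross-validation: participants are split into 4 near-equal outer folds
per run; within each outer training set a 4-fold inner CV selects λ
from 17 log-spaced values in [1e−4, 1e4] by mean squared prediction
error, ties broken toward the stronger penalty. A model at the selected
λ predicts the held-out fold; predictions are pooled across outer folds
and a single Pearson r per parcel per run is computed. 100 runs
re-randomize the fold assignment; one assignment per run is shared by
all parcels so run-to-run variation is isolated from parcel
differences. Degenerate outcomes (zero variance, missing entries) are
skipped with warnings and recorded as missing cells.

Internally the nested loop solves the identical ridge problem in
kernel (dual) form, α = (XXᵀ + λI)⁻¹(y − c), reusing one
eigendecomposition of the training Gram matrix per fold across all
parcels and λ values. This is an exact algebraic rewrite (verified
against the explicit estimator to 1e−8 in the tests), and makes the
full 22 × 100 suite run in about a second.

## Probabilistic index

Pooled moments (mean, sample SD) of all non-missing accuracies define
the Gaussian used for z-scoring; z > 1.96 defines the top tail.
Strictly, 1.96 is the two-sided 5% critical value — the one-sided 95th
percentile is ≈ 1.645 — but 1.96 is kept as the conventional printed
threshold; it is configurable. The inequality is strict, so a cell
exactly at the cutoff is not counted.

Block maxima: per parcel, the k = max(1, round(0.10 · R)) largest
z-scores are summarized by a 90% trimmed mean, interpreted as
discarding floor(n · 0.45) values from each end (the common statistics
toolbox convention), so with ten block values the middle two are
averaged. If trimming would discard everything the median is used with
a warning. Missing cells are excluded everywhere and the per-parcel
effective run count is recorded.

The extreme-value fit defaults to the Gumbel (max) family — the
zero-shape block-maxima limit and the smallest-assumption choice; the
generalized extreme-value family is available. Fits are maximum
likelihood via scipy; degenerate spreads and non-finite likelihoods
raise. The probability index is the upper-tail probability of each
parcel's block maximum under the fitted law; it is strictly decreasing
in the block maximum wherever the survival function is representable in
double precision (it saturates at 1.0 roughly three scales below the
location).

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 52
participants, 22 parcels (25 ICA components minus 3 noise), 597 rest
timepoints, with the following structure:

- **Group maps**: voxels split into contiguous parcel blocks with
  positive dominant weights and signed spillover onto neighbouring
  parcels controlled by an overlap fraction; always full column rank.
- **Group FC template**: a low-rank factor correlation shrunk toward
  identity, projected to the nearest correlation matrix (eigenvalue
  floor 1e−6, single clip-and-rescale pass). Off-diagonals land mostly
  in 0–0.5, typical of parcel-level rsFC.
- **Participant FC**: Fisher-z deviations of scale `fc_variability`
  (default 0.1) around the template, composed of loadings on 5 shared
  edge modes (70% of deviation variance) plus idiosyncratic edge noise
  (30%), then back-transformed and projected to a valid correlation
  matrix. The low-dimensional shared structure mirrors the dominant
  population modes of inter-individual FC variation in real cohorts,
  and is what makes out-of-sample prediction possible at all with
  N = 52 participants and 231 edge features.
- **Contrasts**: signal parcels get y = Xw + ε with a sparse unit-norm
  w (10 nonzero features); the noise variance is solved analytically,
  v<sub>ε</sub> = v<sub>s</sub>(1 − e)/e, so the feature term explains
  the target fraction e (`effect_strength`) of column variance.
  `noise_sd = 0` suppresses noise entirely (exact linear columns);
  null parcels are pure noise matching the signal columns' SD (or
  `noise_sd` when no parcel carries signal).
- **Seeds**: every stage seed derives from the master seed by
  SeedSequence spawning in a fixed order, so cohorts are bit-identical
  per (config, seed) and stages are decoupled.

What the generator does **not** emulate: hemodynamics, autocorrelated
scanner noise, motion, registration error, voxel-level 4D series beyond
small fixture volumes, or empirically calibrated effect sizes (the
study's true between-participant contrast variance is unknown, so
`effect_strength` is a free parameter). Passing tests therefore show
that the chain recovers planted structure and is calibrated under its
own assumptions — not that any particular real dataset is predictable.

## Validation behaviour worth knowing

- Because the 100 runs re-randomize folds on *fixed* data, per-parcel
  accuracies are strongly persistent across runs (between-parcel spread
  ≈ 0.14 vs within-parcel ≈ 0.10 on null cohorts). The total number of
  top-tail flags on a null cohort is therefore overdispersed by roughly
  3.5× relative to an i.i.d.-cell binomial reference; calibration
  checks accordingly average over replicate null cohorts rather than
  reading a single cohort's total.
- Null grand-mean accuracy sits slightly below zero (≈ −0.04): the
  λ-selection mixes a small positive bias from cohort-once
  standardization leakage at weak penalties with a residual fold-mean
  anticorrelation at strong penalties.
- Planted-effect recovery varies with the draw of the sparse weight
  vector: weights whose energy falls mainly outside the shared-mode
  subspace are intrinsically harder to predict out-of-sample, so
  single-cohort accuracies fluctuate more than the 20-replicate
  recovery rate.
- Problem sizes in tests and the acceptance script (e.g. 25 or 10 runs
  per suite in replicate studies, 5 null replicates) were chosen to
  keep the full validation in the tens of seconds while leaving the
  reference single-cohort analyses at the full 22 × 100 scale.

## Known limitations

- The accuracy measure (pooled out-of-sample Pearson r) inherits the
  usual CV-correlation artifacts discussed above; per-fold accuracy
  averaging is deliberately not used, as the analysis convention is one
  coefficient per parcel per run.
- The Gumbel fit is across P = 22 block maxima in real use — a small
  sample for any EVD; the index is a ranking/flagging device, not a
  calibrated p-value.
- Group ICA, first-level GLMs and spatial preprocessing are out of
  scope; the package consumes (or synthesizes) weighted maps, parcel
  time courses and contrast values.
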