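# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The pipeline operates on three aligned objects: a region atlas (per-ROI
metadata: tissue class, limbic vs cortical-association pattern class, lobe,
hippocampus flag, reference-region flag), subject metadata (diagnosis, age,
sex, education in years, APOE ε4 carriership, intracranial volume in mm³,
amyloid status), and one subjects × regions matrix per modality.  Matrices
carry a processing-state tag (`raw`, `global-normalized`,
`reference-scaled`, `icv-adjusted`, `w-score`) and state changes only happen
through the corresponding operations, so the clustering stage can insist on
analysis-ready inputs (global-normalized uptake, ICV-adjusted volumes) and
the w-score maps on pons-scaled uptake.

Analysis-sample selection gates patients on amyloid positivity and controls
on amyloid negativity; subjects failing the gate (or lacking amyloid status)
are excluded with a recorded reason.

## Preprocessing

**Head-size adjustment.**  Per region, β is the ordinary-least-squares slope
of raw volume on intracranial volume fitted in controls only, and every
subject (control and patient alike) receives
`V_adj = V_raw − β (ICV_raw − ICV_mean)`, with `ICV_mean` the control mean.
OLS residual orthogonality makes the adjusted control volumes uncorrelated
with ICV up to numerical precision, and refitting β on adjusted volumes
returns ≈ 0; both properties are asserted in tests.

**Uptake scaling.**  Two scalings with different purposes: division by the
subject's global mean uptake over all non-reference regions (input to
clustering; reference regions are excluded so the two scalings stay
independent), and division by the mean of the reference (pons-like) regions
(input to w-score maps).  Reference columns are dropped from the
reference-scaled output — after scaling, a single reference region is
identically 1 and would only produce degenerate downstream fits.  A caveat
worth stating explicitly: global-mean normalization removes any spatially
uniform component of a subject's uptake pattern, so a uniformly "diffuse"
hypometabolism signature is largely invisible after it.  This is a property
of the normalization, not of this implementation, and it motivates the
choice of uptake templates below.

**Quality screen.**  Total regional volume is regressed on ICV and subjects
beyond a configurable multiple (default 4) of the residual SD are flagged.
Flags are advisory; exclusion is a configuration toggle.  The default
threshold is deliberately loose — the screen replaces a visual check and is
meant to catch gross segmentation failures only.

## w-scores

Per region, a multiple regression of the (analysis-state) value on age, sex
(0/1), education (years) and APOE ε4 (0/1) is fitted in controls;
`w = (observed − predicted) / residual SD` with the residual SD taken at
`n − p` degrees of freedom.  Covariates that are constant in the control
sample are dropped with a warning; a near-zero residual SD is a hard error.
Scores are reversed by default for both modalities so that higher w means
greater neurodegeneration (lower volume, lower uptake).  On the fitting
sample the per-region mean of w is 0 by construction and the SD is
`sqrt((n−p)/(n−1))` ≈ 0.996 at n = 500 — the calibration the acceptance
script reports.

## Unsupervised forest dissimilarity

The contrast class is the standard column-wise bootstrap: each synthetic
column is an independent with-replacement resample of the corresponding real
column, preserving marginals while destroying between-column dependence.  A
classification forest (scikit-learn) separates real from contrast rows;
proximity of two real subjects is the fraction of trees in which they share
a terminal node, counted over all trees by default (an OOB-restricted
variant is a toggle, as is the linear `1 − proximity` transform in place of
the default `sqrt(1 − proximity)`).  `mtry` and `nodesize` are tuned by
out-of-bag misclassification error over a small grid (default: mtry ∈
{√p, p/3, p/2}, nodesize ∈ {1, 5, 10}), ties toward smaller values.  The
desk-scale default is 2 000 trees; published analyses of this kind use
20 000, which is a configuration change.  Stability is assessed by re-running
the forest with fresh seeds and reporting element-wise dissimilarity
differences plus the adjusted Rand index of the downstream labels against
the reference run.

**Sensitivity caveat (measured, and worth knowing).**  Because the forest
keys on multi-region dependence structure, the dissimilarity is
systematically insensitive to group contrasts confined to a small fraction
of regions: a hippocampus-only difference between a limbic-predominant and a
minimal pattern (4 of 44 regions) is essentially invisible at any effect
magnitude — each region's marginal distribution is identical in the real and
contrast classes, so single-feature splits carry no signal and the contrast
surfaces only through higher-order interactions.  We verified that R's
`randomForest` in unsupervised mode behaves identically on the same data.
Recoverable planted subtypes must therefore differ over broad region sets;
this shaped the recovery-experiment templates below and is a real limitation
to keep in mind when interpreting null results on narrow contrasts.

## Embedding, clustering and k selection

Classical (Torgerson) MDS: double-center `−D²/2`, eigendecompose, scale the
top-d eigenvectors by the square roots of their (positive) eigenvalues.
Columns are ordered by descending eigenvalue and sign-fixed by making the
largest-magnitude loading positive, so outputs are reproducible; if fewer
than d eigenvalues are positive the available dimensions are returned with a
warning.  The default d = 3 follows the scree behaviour of this family of
analyses.  Average-linkage (UPGMA) clustering runs on Euclidean distances
between embedded points (scipy linkage; validated against an O(n³)
definitional oracle).  Dendrogram cuts relabel clusters size-descending so
label 1 is always the largest cluster.

The four validation indices are implemented from their definitions
(variance-ratio Calinski–Harabasz; Davies–Bouldin with mean-distance
spreads; Dunn as single-link separation over maximal diameter; silhouette
with singleton score 0) and are computed on the embedding coordinates — the
space in which the clustering operates.  Degenerate geometry yields infinite
sentinels that are excluded from voting but never silently dropped.  The
recommended k is the majority vote of the four per-index optima with ties
toward smaller k; this is a documented proxy for reading the index curves
jointly, and `RunConfig.manual_k` is the faithful path when judgment or
prior knowledge should override the vote.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the study's scale (defaults: 176 amyloid-negative controls, 180
amyloid-positive patients, 44 bilateral-merged regions).

* Controls: per-region baseline values (volumes 1.2–25 cm³, uptake ~5–7.5
  in arbitrary SUVR-like units, fixed given the atlas) modulated
  multiplicatively by age (−0.4 %/year for volumes, −0.2 %/year for uptake),
  sex, education and APOE ε4, plus, for volumes, a head-size term in which
  60 % of a region's volume scales proportionally with relative ICV
  deviation.  Region noise is additive Gaussian (6 % of baseline for
  volumes, 8 % for uptake); uptake rows additionally carry a subject-level
  multiplicative `exp(N(0, 0.1))` factor, so global-mean normalization has
  real work to do.  Demographics are drawn to plausible elderly-cohort
  ranges (age ~ N(74, 7), education ~ N(16, 3), APOE ε4 rate 0.7 in
  patients vs 0.2 in controls, ICV ~ N(1.5e6, 1.5e5) mm³).
* Patients: drawn from subtype templates by prevalence; a template shifts
  region means by its stated effects, expressed in empirical control-SD
  units (negative = neurodegeneration), with reference regions never
  shifted.  The uptake-side template is drawn first; the volume-side
  template equals its position-paired counterpart with probability
  `concordance` (default 0.6) and is an independent prevalence-weighted
  redraw otherwise, giving cross-modality agreement a known closed form:
  `P(match) = c + (1 − c) Σᵢ pᵢ²` when both sides share a template list.
* Default template sets mirror the published subtype families collapsed to
  four: volumes carry limbic-predominant / cortical-predominant / diffuse /
  minimal patterns (prevalences 0.27 / 0.19 / 0.35 / 0.19), uptake carries
  limbic / cortical / limbic-frontal / cortical-posterior patterns
  (0.36 / 0.43 / 0.13 / 0.08) — pattern contrasts rather than uniform
  severity, because of the normalization caveat above.
* `separated_templates()` is the recovery-experiment set: four spatially
  distinct lobe-based patterns at 2.4 control-SD (temporal-limbic, frontal,
  parietal-occipital, diffuse; prevalences 0.30 / 0.25 / 0.25 / 0.20).  Two
  findings fixed this design: narrow contrasts are below the dissimilarity's
  sensitivity (above), and a signature-free "minimal" template forms a
  diffuse central cloud that the validation indices decline to count as one
  cluster even when the labels are perfectly recoverable.  With this set the
  full pipeline recovers the planted k = 4 and labels at ARI ≥ 0.8 across
  seeds, which is what the acceptance script measures.

What the generator does **not** emulate: realistic between-region
correlation beyond the planted patterns and the shared covariate/head-size
factors; scanner and site effects; longitudinal change; mixed pathologies;
the smooth severity continuum of real cohorts.  Passing recovery tests
therefore demonstrate correctness of the pipeline's machinery on separable
structure, not that real FDG/MRI cohorts contain four clean clusters.

## Hypothesis-driven subtyping and axes

The hippocampus-to-cortex ratio is the mean over hippocampus regions divided
by the mean over cortical-association regions (both sets configurable via
the atlas).  Classification is two-step: a provisional label for ratios
strictly below the 25th / above the 75th percentile of the patient sample,
confirmed only when the discordance is real (limbic-predominant requires the
hippocampal composite below the patient median *and* the cortical composite
above it; cortical-predominant the reverse); unconfirmed cases revert to
"Typical".  Ties exactly at a threshold stay Typical-ward and are logged;
all thresholds are returned with the labels.  The rule is scale-invariant,
being built from percentiles and medians.

Axes: typicality is the modality-specific ratio; severity is the summed
non-reference region volume (MRI) or the mean uptake over cortical regions
(FDG).  Both are min–max normalized over the patient sample; the normalized
severity is reversed (1 = most neurodegeneration) so that subtype positions
read naturally on a severity axis, with diffuse-atrophy groups near 1 and
minimal-atrophy groups near 0.  Reference regions are excluded from the
volume sum because severity is a grey-matter measure and the reference
region exists only for uptake scaling.  Pearson correlations between the
four axis pairings are reported as r, r² and two-sided p.

## Cross-modality and group statistics

Crossover tables are plain contingency counts with row-normalized
percentages and an alluvial edge list; overall agreement maps
modality-specific labels to shared classes through an explicit equivalence
map and reports the percentage of coinciding pairs.  Group comparisons use
χ² for categorical and Kruskal–Wallis for continuous variables, with one
Holm–Šidák family across the compared variables
(`adj_i = max_{j≤i} 1 − (1 − p_j)^(m−j+1)`, monotone, capped at 1; computed
via statsmodels and cross-checked against the closed form in tests).  Post
hoc pairwise tests run only where the omnibus survives, with their own
Holm–Šidák family per variable.  Summary tables report mean (sample SD,
n−1 denominator) for continuous and count (%) for categorical variables,
with an optional control reference column.  The significance level is a
single configured α (default 0.05), logged with the results.

## Numerical choices and problem sizes

Seeds thread explicitly through every stochastic component (generator,
contrast sampling, forest, stability runs); identical seeds give
bit-identical cohorts and dissimilarities.  Eigen-decompositions use
symmetric solvers with a relative tolerance of `n·eps·|λ₁|` for calling an
eigenvalue positive.  The test suite and acceptance script run at deliberate
desk scale — 500-control calibration samples, 100 random oracle instances,
five-seed forest checks, five recovery cohorts at n = 180 with 2 000 trees,
200 null simulations — sizes chosen so the whole validation completes in a
few minutes while keeping every Monte-Carlo margin comfortable.

## Known limitations

* The dissimilarity's insensitivity to narrow contrasts (above) means
  hippocampus-only subtypes need either broader involvement or a different
  dissimilarity to be detectable.
* The index majority vote is a proxy for human reading of the index curves;
  on ambiguous geometry the four indices legitimately disagree and the
  manual override exists for exactly that case.
* The generator's independence assumptions make its cohorts easier to
  cluster than real data at matched effect sizes; conclusions about real
  cohorts require the real data.
* WMH volume is treated as a given metadata column (its ICV adjustment
  reuses the volume machinery on a one-column matrix); no imaging-level
  processing is in scope.
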