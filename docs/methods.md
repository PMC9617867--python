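# Methods and design notes

This note documents the statistical model behind `pesmorph`, the choices
made where the procedure is genuinely open, and what the synthetic data do
— and do not — establish about behaviour on real osteometric assemblages.

## Measurement model and reliability

Raw input is a long table of repeated calliper measurements (mm) on
skeletal elements. The working value of each measurement is the arithmetic
mean of its replicates (any count ≥ 2 is accepted; 3 is the protocol
default and what the generator produces). Reliability is summarised per
measurement by an intraclass correlation computed from explicit two-way
ANOVA mean squares. The default variant is ICC(3,1) — two-way
mixed-effects, consistency, single rating — because one fixed operator
measuring every specimen is a mixed-effects design and downstream analyses
consume single (averaged) values; ICC(1,1), ICC(2,1) and the average-of-k
forms are available because reliability conventions differ between labs
and no single variant can be assumed. Measurements with ICC below a
configurable floor (default 0.9) are flagged but not removed: the flag is
a data-quality signal, not a filter. The repeat SD is also reported as a
proportion of the specimen mean, since absolute repeat error tends to be
proportionally larger on small bones.

Specimens missing any required measurement leave the pipeline for that
element with a warning. Classifying fragmentary material is an explicit
non-goal; supporting it would require missing-data discriminant machinery
that this package does not attempt.

## Size, shape, and size groups

Size is the geometric mean (GM) of a specimen's retained measurements;
shape is the vector of base-10 log-shape ratios log10(x/GM). These sum to
zero by construction, so the shape covariance is singular along the unit
vector — a fact every downstream consumer must respect (see Ordination).

Size-group assignment is visual in field practice. For reproducibility the
primary path is explicit user-supplied GM cut-points; the automatic
fallback runs 1-D k-means (k = number of groups) on species median GM and
places boundaries at midpoints between adjacent cluster edges. A species
joins every group that its central 95% GM interval intersects, so
size-straddling taxa are analysed in both neighbouring groups. Unknowns
are placed by GM into every group interval padded by 2.5% of its width;
an unknown smaller (larger) than the whole training range is assigned to
the nearest group and flagged `below_training_range`
(`above_training_range`) rather than rejected, because out-of-range size
is itself evidence worth reporting.

## Measurement redundancy

Calliper protocols are deliberately over-complete. The stepwise test drops
measurements greedily while the *ordination* of shape is preserved, where
preservation is measured as the Pearson correlation between the vectorised
upper triangles of Euclidean inter-specimen distance matrices computed
from log-shape ratios of the full versus reduced measurement sets (a
Mantel-style congruence without a permutation p-value, which a greedy
criterion does not need). Shape ratios are recomputed from the reduced set
at every step, since removing a column changes the geometric mean.
Measurements that rarely survive archaeologically (e.g. epiphysis-bearing
dimensions) can be force-dropped before the greedy phase, and anchor
measurements force-kept. Ties in congruence (which occur for exactly
duplicated columns, up to float noise below 1e-12) are broken by dropping
the lexicographically last name, making the drop order deterministic.

One consequence worth knowing: dropping one copy of an exactly duplicated
measurement does *not* give congruence exactly 1.0, because the geometric
mean re-centres every specimen's shape vector when a column leaves; the
congruence is merely far higher than for any informative column (≈ 0.99 in
the test fixtures). The default threshold is 0.99 with element-specific
retained-measurement floors of 7 (astragalus, metatarsal IV) and 9
(calcaneus), matching common practice for these elements.

## Ordination and MANOVA

PCA is covariance-based on centred shape rows, components ordered by
variance; each loading column's largest-magnitude entry is oriented
positive so scores are reproducible across platforms. Unknowns are
projected as (row − centre) · loadings.

MANOVA of shape against size (continuous log10 GM), age class, or sex uses
Wilks' Λ with Rao's F approximation (Pillai's trace available). Because
shape rows sum to zero, the response is first rotated onto its leading
full-rank subspace via SVD — Wilks' Λ is invariant to this choice of
basis, which the tests verify, and it avoids the arbitrary alternative of
deleting one measurement column. With a single response column the
statistic degenerates to the ordinary regression F test, computed exactly.
Insufficient residual degrees of freedom raise an explicit error advising
dimension reduction rather than silently returning a defective fit.
Parametric p-values are the default; a permutation option (predictor rows
shuffled) exists because both conventions are common in morphometrics.
Intraspecific age and sex tests run per species only where at least 8
specimens are available — below that the test is noise.

## Discriminant classification

Within each element × size group, genera are modelled as Gaussians with a
common pooled covariance in form space: the log10 of every retained
measurement. A specimen's log measurements decompose exactly as
log10 GM · **1** + shape, and LDA is invariant to invertible affine maps,
so classifying logged measurements is identical in outcome to classifying
[size ∥ shape] coordinates; logged measurements are the default and the
raw scale is deliberately not offered, since raw-scale LDA is a different
(and worse-behaved) model. Canonical axes come from the generalized
eigenproblem between/within, scaled to unit pooled within-group variance.
Priors default to training-set proportions (the common default of
discriminant software); equal priors are available for archaeological use
where collection composition is not a sensible prior.

Cross-validation defaults to exact leave-one-out, which is deterministic
and exhaustive; a stratified Monte-Carlo holdout (default 1000 repetitions)
is provided as an alternative, and the report always records which scheme
and seed produced it. Folds whose reduced training set loses a genus or a
full-rank covariance are counted as misclassified and logged — a
conservative convention that cannot inflate the hit ratio.

Hit ratios are judged against the maximum chance criterion
Cmax = max nᵢ/N, the proportional chance criterion Cpro = Σ(nᵢ/N)², both
multiplied by 1.25 to form thresholds that must be *strictly* exceeded,
and Press's Q = (N − nK)²/(N(K−1)) compared with the χ²(1) upper-0.1
quantile (≈ 2.706). A group passes only on the conjunction of all three.

Unknowns receive Gaussian-Bayes posteriors per genus (the argmax is the
call) and a typicality probability per genus: the χ²(p) tail of the
squared Mahalanobis distance to the group mean under the pooled
covariance. A specimen whose typicality is below α (default 0.01) for
*every* genus is flagged atypical — a candidate member of a taxon missing
from the training set — but keeps its nearest-genus call, since the flag
qualifies rather than replaces the classification. Classification is to
genus only; species labels are carried through but never predicted,
because per-species samples in realistic training sets are too small.

One behavioural note: under label permutation, leave-one-out with priors
recomputed on each fold from training proportions is slightly
anti-conservative (the held-out specimen's own class loses a count, biasing
the fold against it), so the chance-level calibration test uses equal
priors, for which LOOCV sits exactly at Cpro.

## The synthetic generator

The generator emulates the statistical anatomy the analysis assumes, in
log space: per specimen, log10 measurements = log10 GM · **1** + species
mean shape + allometric slope · (log10 GM − species mean) + age offset +
centred multivariate noise, with log-normal per-species size, sexual size
dimorphism (males shifted in log10 GM only — sex does not affect shape, as
observed in macropods), juveniles reduced in size and offset in shape
along a common ontogenetic direction (subadults get half of each), and
replicates multiplied by a log-normal operator-error factor. All shape
vectors sum to zero; all randomness flows from one seed.

The reference fixture (`demo_config`) has 8 genera, 12 species and ~520
modern specimens in three size clusters — the scale of a realistic museum
training set — with genus mean shapes on orthogonal sum-zero contrasts
0.10 log-units long against a within-species shape SD of 0.012, i.e.
genera separated by several Mahalanobis units. Default operator error is a
1% CV, giving ICCs near 0.999, comfortably above the 0.9 floor. Sizes span
roughly 8–33 mm GM with sd(log10 GM) = 0.04 per species, which makes a few
species straddle size-group boundaries — intentionally, since real
assemblages do. Archaeological unknowns default to two per genus across
seven strata; `make_novel_taxon` adds an archaeological-only taxon whose
mean shape sits at an exact requested Mahalanobis distance from the
nearest genus while copying the smallest species' size, so detection must
come from shape.

What passing tests on this generator show: the algebra, the estimators,
the chance-corrected criteria, the typicality flag and the orchestration
behave correctly under the model's own assumptions. What they do not show:
robustness to non-Gaussian shape variation, unequal within-group
covariances (real training sets are heteroscedastic), correlated
measurement error, taphonomic loss, or mislabelled reference specimens.
Hit ratios of 1.0 on the fixture reflect its deliberately clean separation
and should not be read as a performance claim for real bones.

## Numerical conventions

- PCA/rank decisions use a relative singular-value tolerance of 1e-9;
  pooled covariances are declared singular below a relative eigenvalue of
  1e-12.
- Posteriors are computed via log-space softmax of −½ Mahalanobis² + log
  prior; they are exact Gaussian-Bayes quantities, verified against
  brute-force densities to 1e-8 in the tests.
- Threshold comparisons for the chance criteria are strict (a hit ratio
  exactly equal to a threshold fails).
- Problem sizes in the test suite (e.g. 200 chance-level replicates at
  n = 45, 1000 MANOVA-uniformity replicates at n = 24, 300 novel-taxon
  specimens) were chosen so that Monte-Carlo standard errors are small
  relative to the asserted tolerances.

## Known limitations

- No fragmentary-specimen support (complete cases only).
- No quadratic or regularised discriminants; heteroscedastic training sets
  are modelled with a single pooled covariance regardless.
- Size-group cut-points derived by k-means are a reproducible stand-in for
  the visual groupings used in practice, not a claim about where those
  boundaries "really" are.
- The redundancy statistic (distance-matrix congruence) is one reasonable
  operationalisation of "without affecting the ordination"; protocols
  based on raw-measurement correlation or PCA congruence would retain
  different sets.
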