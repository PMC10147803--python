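# Methods

## Model and procedure

`eoscluster` stratifies Early Onset Scoliosis patients within each
etiology by fuzzy C-means (FCM) clustering of six pre-operative
clinical indices: age, major curve Cobb angle, kyphosis, levels in the
major curve, levels in kyphosis, and the deformity index (Cobb /
kyphosis).  FCM assigns each subject a membership vector over clusters
(non-negative, summing to one) by alternating minimisation of the
fuzzified within-cluster sum of squares

J(U, V) = Σᵢ Σⱼ u_ij^m ‖x_i − v_j‖², with the standard membership
update u_ij = 1 / Σ_l (d_ij/d_il)^{2/(m−1)} and centroid update
v_j = Σᵢ u_ij^m x_i / Σᵢ u_ij^m (Euclidean distance).  Each
alternating step cannot increase J; the implementation records the
objective trace and the test suite asserts monotonicity on every fit.

The cluster count is chosen by refitting over k = 2..6 with identical
configuration and seed and keeping the k with the highest **average
membership**, defined as the mean over subjects of their maximum
membership.  This row-maximum aggregation is a deliberate
interpretation: it is the only per-subject scalar that serves
simultaneously as a confidence measure (for the k criterion) and as an
outlier score (against the 0.6 floor), so the same quantity drives
both decisions.  Ties break to the smaller k (parsimony).  Note k = 1
is never a candidate; on structureless data the criterion returns
k = 2 with visibly low average membership, and the library logs a
weak-structure warning rather than inventing a one-cluster answer.

Subjects whose maximum membership is **strictly below 0.6** are flagged
as outliers.  The fitted model is *not* refit after exclusion:
assignments are frozen at fit time and outliers are merely excluded
from summary tables and statistics.  This is the minimal, deterministic
reading of exclusion; a `refit_after_exclusion` switch (default off)
refits at the selected k on retained subjects and re-evaluates everyone
against the new centroids, for users who prefer the alternative
reading.

Clusters are renumbered 1..k in ascending order of the mean raw Cobb
angle of their retained members (ties keep the lower original index; a
cluster with no retained members falls back to its centroid's Cobb).
Per index, clusters are compared with a one-way fixed-effects ANOVA and
Tukey's HSD post-hoc test (studentized range; Tukey–Kramer harmonic
correction for unequal group sizes).

## Feature scaling

The six indices mix years (0–10), degrees (10–150), counts (1–17) and
a ratio.  Without scaling, the degree-valued features dominate the
Euclidean metric, so each etiology's feature matrix is z-scored per
column before clustering.  The SD convention is the sample SD
(divisor n − 1), recorded explicitly so tests can assert exact values;
constant columns map to zero with their SD stored as 1 to keep the
transform invertible.  The scaling parameters are stored in the fitted
model and reused verbatim when scoring new patients, so a new patient
is projected into exactly the space the model was fitted in.

The deformity index divides Cobb by kyphosis; hypokyphotic or lordotic
sagittal profiles would make the ratio blow up or change sign, so
kyphosis is floored at 1° (configurable) inside the ratio while the raw
(possibly small or negative) kyphosis value is kept as the kyphosis
feature itself.  Both kyphosis and the deformity index enter the
feature set even though they are functionally related — the six-index
list is the method's definition, and the redundancy is intentional.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| fuzzifier m | 2.0 | canonical FCM softness; makes memberships inverse-square-distance ratios |
| tolerance | 1e-6 | max absolute membership change declaring convergence |
| max iterations | 300 | cap per start; non-convergence is logged, the model remains usable |
| starts | 10 | Dirichlet(1) random membership initialisations; lowest final objective wins |
| k range | 2..6 | caps well above the expected optimum of 3 while keeping runs instant |
| membership floor | 0.6 | outlier threshold; strictly-below reading (0.6 itself is retained) |
| α | 0.01 | significance level for ANOVA and Tukey |
| kyphosis floor | 1° | deformity-index denominator floor |

All randomness flows from a single integer seed through
`numpy.random.default_rng`, so a run is reproducible bit-for-bit;
repeated runs with the same input, config and seed produce
byte-identical JSON outputs.

Numerical notes: membership ratios are normalised by the row-minimum
distance before exponentiation, which is algebraically identical but
avoids overflow for small m (the m → 1 hard-clustering limit is tested
against a Lloyd k-means oracle at m = 1.05); a subject coinciding with
a centroid receives membership 1 there, splitting equally if several
centroids coincide; an empty cluster (zero total weight) is re-seeded
at the subject with the worst maximum membership and logged.

## Synthetic cohorts

Real EOS registries are private, so the generator emulates the
analysis-relevant structure of such cohorts: per etiology, a
three-component Gaussian mixture over the five measured indices with
diagonal covariance, truncated to valid ranges (age clipped to
[0.25, 10] years, angles to [10, 150]°, level counts rounded into
[1, 17]), plus a configurable fraction (default 5%, matching the
exclusion rates such cohorts report) of outliers drawn uniformly over
the full valid ranges.  The deformity index is never sampled; it is
computed from the sampled Cobb and kyphosis exactly as for real data.
Component labels and outlier flags are returned as hidden ground truth
for recovery tests.

The default per-etiology component means and SDs live in the versioned
`data/default_cohorts.json`, not in code, so they can be replaced if
registry-derived values become available.  They are invented plausible
clinical magnitudes chosen once, with these deliberate qualitative
properties:

* components are ordered by ascending mean Cobb and separated pairwise
  by at least ~4 within-component SDs in several indices — the "well
  separated" regime the membership criterion needs;
* neuromuscular and syndromic cohorts each contain exactly one
  kyphosis-dominant component (mean kyphosis > mean Cobb, expected
  deformity index < 1); congenital and idiopathic components are all
  Cobb-dominant, their severe component combining marked kyphosis with
  a deformity index still above one;
* the congenital and idiopathic severe components span *fewer* levels
  than the mid components (short sharp curves versus long sweeping
  curves — clinically typical of congenital EOS).  Besides realism,
  this makes the three components non-collinear in feature space.
  That matters: for three near-collinear, equally spaced components the
  average-membership criterion sits at its k = 2 / k = 3 decision
  boundary (merging two clusters costs little membership when the third
  lies on the same axis), and selection becomes a coin flip.  The
  default cohorts therefore embody geometries in which the criterion is
  actually informative; users probing collinear mixtures should expect
  k = 2 selections.

What the generator does **not** emulate: correlations between indices
within a component (a full-covariance hook exists for stress tests),
measurement error and multi-observer variation, longitudinal visits,
missing-data mechanisms, and the real registries' cluster shapes —
Tables of per-cluster means in the source literature are not public in
usable form, so no claim is made that the default components match
real-cohort clusters.  Passing tests demonstrate that the *method*
recovers known structure under its own assumptions, not that real EOS
cohorts contain three clusters.

Sampling properties asserted in tests: exact outlier counts
(round(fraction × n)), multinomial component counts within binomial
99% bounds, empirical component means within ~3 SE at large n
(clipping is negligible for mid-range means), and per-seed determinism.

## Problem sizes

The package's study conditions use n = 250 subjects per etiology for
the headline cluster-count result, 52 seeded replicates for the
recovery rate, 50 replicates at n = 200 with 5% injected outliers for
outlier recall, and 2000 null replicates (three groups of 20) for the
ANOVA type-I calibration.  These sizes give stable rates while keeping
any single command in the seconds-to-a-minute range.

## Known limitations

* The average-membership criterion is biased toward small k; it works
  in the well-separated regime but is not a general-purpose validity
  index (alternatives such as Xie–Beni are intentionally out of the
  selection path).
* Outlier recall under the 0.6 rule depends on cluster geometry, not
  cluster tightness: FCM memberships are ratios of distances, so a
  uniform-range point that happens to be markedly closer to one
  centroid than the others is retained no matter how far away it is.
  Mean recall at the default conditions is ~0.85, not 1.
* ANOVA assumes within-cluster normality and equal variances; with the
  generator's Gaussian components this holds by construction, and no
  robustness claim is made for real cohorts.
* No multiple-testing correction is applied across the six indices
  beyond Tukey's within-index adjustment, mirroring the source
  methodology.
* Between-etiology comparisons are not part of the pipeline; the same
  statistical machinery can be applied across etiology-cluster groups,
  but no design for that comparison is defined here.
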