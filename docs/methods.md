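# Methods

## The model

`hdss` represents each person-timepoint questionnaire response as a vector
in a high-dimensional symptom space.  For a CBCL-style instrument the raw
design matrix has one column per ordinal item (119 items scored 0/1/2,
entered as raw scores) plus demographic columns: race and gender expanded
as indicator variables (`onehot`, the default) or integer-coded single
columns (`compact`, which reproduces the 119 + 3 = 122 column count some
analyses quote), and age as a real column.  Every feature is then z-scored
— mean 0, SD 1 with the population (divide-by-n) convention — over the
pooled person-timepoint observations, so that all timepoints live in one
comparable space and each feature contributes one equally weighted
dimension.  The fitted means and SDs are frozen with the space, making the
transform invertible and letting new raw observations be projected into
the same coordinates.

Dissimilarity between observations i and j is the plain Euclidean
distance

    d_ij = sqrt( sum_k (z_ik - z_jk)^2 ),

so identical response profiles are at distance 0.  Distances are always
computed in standardized coordinates; raw-space distances exist behind a
flag for diagnostics only.  A parallel 5-dimensional space built from the
broad-band scale T-scores (total problems, internalizing, externalizing,
attention, somatic) supports the low-dimensional severity comparison.

### Centroid analysis

The *average person vector* is the feature-wise mean of the cohort (or of
a demographic stratum); in the standardized coordinates of the space it
was fitted on, the global centroid is exactly the origin, so an
observation's centroid distance is the L2 norm of its standardized row.
The package also defines a **person severity index**: the person's
standardized rows are averaged over their timepoints and the index is the
Euclidean distance of that time-averaged position from the centroid.
Year-to-year fluctuation cancels in the mean position, so the index
measures sustained displacement over the follow-up; it is the geometric
mirror of a latent "chronic severity" defined as the norm of a
time-averaged factor score, which is why the simulator's recovery check
pairs exactly these two quantities.

Severity regressions are ordinary least squares of centroid distance on
the DSM-proxy diagnosis count (optionally with covariates), reported with
slope, t, p, adjusted R², and BIC.  BIC uses the Gaussian likelihood with
the MLE variance and counts intercept + slopes + variance as parameters
(k = p + 2), which is stated here because BIC conventions differ across
software.  The distance-vs-total-symptoms relation is summarized by a
Pearson correlation plus the simple-regression slope.

### Scoring and clinical status

Scale raw scores are item sums over a user- or simulator-supplied scale
map with two families: `hitop` broad-band dimensions and `dsm_proxy`
DSM-oriented scales.  T-scores are sample-referenced, T = 50 + 10·z
against a designated reference sample (the baseline timepoint by default,
so longitudinal change is expressed on a frozen metric); licensed
published norm tables are deliberately not reproduced, and T ≥ 65 keeps
its meaning of +1.5 reference SDs.  The threshold rule is inclusive
(T exactly 65 is elevated).  The diagnosis count is the number of elevated
dsm_proxy scales; "total-problems clinical" thresholds the total scale.

### Embedding and the clinical boundary

The joint distance matrix over all person-timepoint observations is
embedded into 2-D with metric MDS.  The SMACOF stress-majorization solver
is implemented in the package so that the per-iteration raw stress is
recorded and its guaranteed monotone decrease asserted on every run; the
first start is the classical-scaling (Torgerson) solution, remaining
starts are random, and the lowest-stress run wins.  Iteration stops when
the relative stress decrease falls below `tol` (default 1e-6, max 300
iterations).  Classical scaling is also exposed as a deterministic
no-restart alternative (`method="classical"`).  Embeddings are
sign/rotation ambiguous; all downstream quantities (distances, angles
between boundary normals) are rotation invariant.

A logistic regression on the two embedding dimensions defines the
clinical/non-clinical frontier at predicted probability 0.5, with
clinical status given by Total Problems T ≥ 65.  A fixed tiny ridge
(1e-8) keeps the maximum-likelihood fit finite when the classes are
perfectly separable; a point exactly on the line is classified clinical
(conservative tie rule).  Trajectories connect each person's positions in
the joint embedding across timepoints; a transition event is a change of
boundary-region label between consecutive timepoints (improved = clinical
to non-clinical), attributed to the step, with no interpolation within
the year.  An option uses raw T-score status instead of the geometric
region labels.

### Category geometry

For overlapping diagnostic categories (comorbid observations count in
every category they hold), the K×K summary matrix holds mean Euclidean
distances: diagonal cells over unordered pairs of distinct members of one
category, off-diagonal cells over cross-category pairs with self-pairs
excluded.  Baseline observations only, by default, with distances taken
from the full-dimensional matrix rather than the 2-D projection (the
embedding-based variant is available).  The headline summary (M_within,
SD_within, M_between, SD_between) is computed over category-level cell
values — diagonal cells, and upper-triangle off-diagonal cells — with
sample (n−1) SDs; a pooled option weights cells by pair counts instead,
since either aggregation level is defensible.

## The synthetic cohort generator

The simulator emulates the shape of a large adolescent questionnaire
cohort so every stage is testable without restricted data.  Mechanism
(probit graded response):

- Five correlated latent severity factors (exchangeable correlation 0.45
  by default) follow an AR(1) process over 4 annual timepoints:
  θ_t = drift + ρ·θ_{t−1} + sqrt(1−ρ²)·η_t with ρ = 0.7, stationary when
  drift = 0.
- Each of the 119 items loads 1.0 on a dominant factor (assigned
  round-robin); a transdiagnostic share of items (30% in the study-like
  preset) additionally loads 0.6 on two other random factors.
- The item propensity is x = Λθ + ε with unit-normal ε, cut into 0/1/2 at
  shared thresholds τ1 = −0.25, τ2 = 0.85 (response rates roughly
  0.43/0.26/0.31).
- Demographics (race, gender, baseline age 9-11 advancing annually) are
  sampled independently of the factors; a `confound_age` switch couples
  age to the first factor to exercise stratified centroids.
- All randomness flows from one root seed through four spawned
  sub-streams (structure, factor scores, item noise, demographics).

The default scale map groups items by dominant planted factor into five
DSM-oriented scales and the broad-band family (total problems = all
items).  Presets: `paper_like` (n = 1000, the study-like condition),
`disjoint` (no overlap, uncorrelated factors), `high_overlap` (60%
transdiagnostic share), `improving` (drift −0.15 per factor per year).

**Cutpoint choice.**  The shared thresholds sit near the propensity
median so that all three response categories are well populated and the
ordinal items carry maximal information about latent severity.  Real
checklist items are far more zero-inflated (often 70-90% "not at all"),
and that zero-inflation matters: with strongly floored items, profiles of
low-severity people collapse onto the all-zero response and the
centroid-distance/latent-severity correlation degrades sharply (we
measured r dropping from ~0.86 to ~0.3 when moving the lower cutpoint a
full SD above the median).  Passing recovery tests on this generator
therefore demonstrates that the geometry is implemented correctly and
informative under favorable measurement, not that a real heavily floored
instrument would identify latent severity equally well.

Other features of real cohorts the generator does not emulate: per-item
difficulty/loading heterogeneity, missingness and attrition, site and
informant effects, measurement non-invariance across demographic groups,
and the dependence of symptom endorsement on demographics (by default).

## Numerical and design choices

- Population-SD standardization; constant features become all-zero
  columns and are flagged rather than raising, so degenerate simulations
  run.
- The two demographic encoding dialects exist because the one-column-per-
  demographic reading ("122 dimensions") cannot be reconstructed
  unambiguously; `onehot` is the statistically clean default, `compact`
  mirrors the quoted dimension count.
- The within/between gap experiment varies only the transdiagnostic share
  while holding the factor correlation fixed, isolating item overlap as
  the mechanism that shrinks the gap.
- The severity-regression predictor of record is the diagnosis count;
  covariates may be added but the reported slope/t/p stay those of the
  count.
- SMACOF restarts default to 4 in the library; the end-to-end pipeline
  uses the classical warm start only (`mds_n_init=1`): on these distance
  matrices random restarts converge to visibly worse stress than the
  classical-scaling start (measured ~213M vs ~200M raw stress on the
  4000-observation study-like run), so the extra starts buy nothing.
- Problem sizes: the bundled study-like runs use n = 1000 persons × 4
  timepoints (a 4000-observation joint embedding); recovery and
  gap experiments in the test suite use n = 60-1000 as noted per test,
  chosen so the full suite runs in minutes on a laptop.
- Pipelines skip writing the O(n²) distance CSV above 2000 observations
  (the matrix is recomputed in memory downstream); all other artifacts are
  written with 17 significant digits, and a rerun under the same seed
  reproduces byte-identical numeric files (hashed in `manifest.json`).

## Known limitations

- Distance from the centroid is a two-sided norm: people *below* average
  on every symptom also sit away from the centroid.  On near-symmetric
  score distributions this folds the distance-severity relation (visible
  in the 5-dimensional scale space, where the correlation with total
  symptoms is much weaker than in the item space).  On heavily
  right-skewed real instruments the folding is mild because the centroid
  sits near the floor.
- Metric MDS at O(n²) memory and time is practical to a few thousand
  observations; no landmark/out-of-sample extension is provided beyond
  refitting.
- The boundary is a single straight line in the 2-D projection; it
  inherits whatever distortion the projection introduces.
- Sample-referenced T-scores are not exchangeable with published
  instrument norms; absolute prevalence of "clinical" status depends on
  the reference sample chosen.
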