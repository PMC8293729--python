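# Methods

## The problem

Digital maps of British woodland record broad habitat (broadleaved,
conifer, mixed) but not tree species, while the species composition of most
privately owned stands is confidential. The analysis implemented here
predicts which broadleaved-woodland polygons contain oak-dominated stands
(*Quercus robur* / *Q. petraea*, ≥ 60% canopy) by combining three
information sources of different character:

1. fine-grained stand records from the public forest estate, usable as
   presence/absence training data;
2. biophysical site rasters (climate, soil, topography) at 50 m;
3. regional inventory summaries — total stocked-oak area and the elevation
   distribution of a small random-stratified sample of oak stands — that
   describe the *whole* (mostly private) resource without revealing
   locations.

A species-distribution model trained on (1) and (2) estimates ecological
suitability; the novel step is post-processing the suitability raster with
(3). Because centuries of management have left real oak woodland on sites
that are not simply the most ecologically suitable ones, a pure
suitability ranking misallocates area. Constraining the ranked selection to
the surveyed elevation distribution corrects this, class by class.

## Pipeline

**Training data.** Presence pixels are all 50 m pixels of training-layer
stands with an oak component ≥ 60% of stand area (optionally subsampled by
`presence_fraction`, default 0.5); absence candidates are pixels of
broadleaved stands with oak absent or ≤ 10%. Stands in between belong to
neither class. Fifteen balanced pseudo-absence replicates (each exactly the
presence count, sampled without replacement within a replicate,
independently across replicates) hold the prevalence at 0.5 while covering
more of the environmental envelope than any single absence set.

**Predictor screening.** Per region, predictors are pruned until every
pairwise |r| ≤ 0.7 and every variance inflation factor ≤ 10 (both
configurable; the auxiliary regressions are centered). Among an offending
correlated set, the variable with the least univariate explained variance
for the presence/absence response is removed first, so the screen keeps
the more informative member of each correlated pair.

**Ensemble.** Four learner families — logistic GLM, gradient-boosted trees
(100 trees, depth 3), random forest (100 trees) and a single-hidden-layer
neural network (8 units) — are fitted per region with fixed default
hyperparameters; there is no tuning. For each of the 15 replicates, a
stratified 50/50 train/test split is drawn `n_repeats` times (default 30).
Each run is scored on its held-out half with the true skill statistic
TSS = sensitivity + specificity − 1, evaluated at the TSS-maximizing
threshold on a 0.01 grid (ties to the smallest threshold). Runs that raise
a fitting error or produce non-finite predictions are kept in the ledger as
unconverged and excluded from averaging; algorithms whose converged
fraction falls below 0.5 in a region are dropped from that region's
ensemble. The regional probability raster is the per-pixel weighted mean of
all converged runs' probability surfaces with weights max(TSS, 0) —
negative-skill runs contribute nothing, keeping the result a convex
combination. A two-stage variant (average within algorithm, then weight
algorithms by mean TSS) is available behind a flag; the single-stage
default is equivalent in expectation and simpler to audit.

**Masking and filtering.** Pixels outside broadleaved indicative forest
types (broadleaved, mixed-predominantly-broadleaved, coppice,
coppice-with-standards) are set to zero and made ineligible. Eligible
pixels are ranked by descending probability with ties broken by (row, col),
which makes every selection bit-reproducible. Two selections are formed:

* *Area filter*: the first n ranked pixels with n = max{k : k × 0.25 ha ≤
  regional area target} — "up to" is read as never exceeding the target (a
  round-to-nearest mode exists). If the eligible pool is smaller, the whole
  pool is taken and the deficit recorded.
* *Elevation filter*: pixels are binned by the DEM value at their centre
  into half-open 10 m classes (0–9, 10–19, …); each class takes its
  top-ranked pixels until the class quota is met. The quota histogram is
  the surveyed sample histogram rescaled (largest-remainder) so its total
  equals the area target in pixels; rescaling is exposed as an option
  because the survey counts only a fraction of stands. Classes with too few
  eligible pixels record a shortfall — deficits are never reallocated to
  neighbouring classes, which would distort the target distribution.

A diagnostic step forces probability 1 at the training presence pixels and
reports the signed mean of (1 − p) over them; a value near zero means the
model already ranks its own training stands at the top. The flag
`apply_manual_adjustment` optionally applies the adjusted raster before
ranking (default off). The two selections' probability values are compared
with a two-sample Kolmogorov–Smirnov test (asymptotic p): forcing pixels
into the surveyed elevation distribution admits a low-probability tail the
area-only selection never reaches, so D > 0 is the expected signature.

**Validation.** A held-out site is *coincident* when at least one selected
pixel centre lies inside its polygon (any-overlap; a buffer option serves
point-located sites). The coincidence success rate — the model's
sensitivity — is tested with a two-sided exact binomial test
(minimum-likelihood tail sum, the `binom.test` convention) against a null
proportion of 0.5, and bracketed by an exact Clopper–Pearson interval.
Both choices are deliberate: p₀ = 0.5 is the unique null reproducing the
method's reference p-value for 35 successes in 64 trials, and
Clopper–Pearson is the only standard interval whose bounds round to the
reference integer percentages for both 35/64 and 53/64 (Wilson's does
not). Both are exposed as parameters.

## The synthetic landscape

Real British forest and site data are confidential or bulky; the
`synthetic` module generates landscapes with the statistical structure the
analysis assumes, from a single seed.

*Covariates.* The DEM is smoothed white noise (Gaussian filter, correlation
length ≈ one tenth of the grid) scaled to a relief of `roughness` metres
(default 350, an upland-margin landscape). Accumulated temperature
(AT, −2.5 dd m⁻¹), climatic moisture deficit (CMD, −0.45 mm m⁻¹) and wind
exposure (DAMS, +0.018 m⁻¹) follow the DEM through fixed lapse
coefficients plus independent autocorrelated noise whose amplitude scales
with relief — so a flat landscape has constant covariates, and the default
landscape has |r(DEM, ·)| around 0.5–0.85, high enough that collinearity
screening has real work to do (typically it removes DEM or one climate
proxy) but not degenerate. Soil moisture and nutrient regimes are ordinal
1–5 fields from quantile-thresholded autocorrelated surfaces. Regions are
contiguous vertical bands.

*Stands.* The grid is tessellated into contiguous stands of 5–30 ha by
region-growing along a serpentine pixel path with run lengths drawn
uniformly in pixel units. The path construction guarantees exact area
bounds, full coverage with no overlaps, and boundaries on pixel edges, so
the label raster and derived polygons agree exactly. Each stand gets an
indicative forest type (55% broadleaved, 25% conifer, 12% mixed, 8% other)
and integer species percentages summing to 100; oak in non-oak-dominated
broadleaved stands follows a zero-inflated mixture (55% none, 25% minor
≤ 10%, 20% intermediate 11–55%), matching the empirical pattern that most
broadleaved woodland carries little oak and giving the absence rule a
realistic candidate pool.

*Truth and occupancy.* Suitability is a logistic niche over standardized
covariates with an explicit elevation optimum:
logit = β·z − ((DEM − opt)/tol)², default opt = 150 m, tol = 90 m.
Stands are split into ownership cohorts (35% public estate). Within each
region × cohort, broadleaved stands are occupied from the top of a score
ranking until 25% of the cohort's broadleaved area is filled. Public
stands rank by pure suitability; private stands rank by suitability
evaluated `management_bias` metres higher (default 120 m) — DEM-coupled
covariates are shifted through their lapse slopes and the optimum term
moves with them — so truly occupied private woodland sits systematically
below the suitability optimum by a known, recoverable displacement. With
zero bias both cohorts collapse to top-suitability occupancy. This
two-cohort structure mirrors the real data-generating process the analysis
faces: training data come from the estate (sites chosen for suitability),
while the inventory histogram and the validation sites describe the
management-displaced private resource. It is exactly the structure the
elevation filter exists to correct, and with the bias at zero it vanishes.

*Inventory products.* Regional area targets equal occupied pixels × 0.25 ha
(optional Gaussian noise). Elevation histograms come from a random sample
of occupied stands covering at least `sample_fraction` (default 0.006,
the survey's sampling intensity) of the occupied area — with a floor of 20
stands per region, because at desk-scale landscapes the raw fraction would
sample less than one stand and the histogram's precision, which in the
real survey comes from its large absolute plot count, would be lost.
Validation sites are up to 64 private occupied stands; they are disjoint
from all public training stands by construction of the tessellation.

## What the synthetic tests do and do not show

Passing end-to-end tests show that the pipeline recovers a known niche with
high skill (random-forest median TSS ≥ 0.8 on clean landscapes), that the
elevation filter strictly improves coincidence when occupancy is
bias-displaced, and that it is statistically neutral when it is not. They
do not show real-world performance: the generator has no spatial sampling
artefacts, no mapping error in stand boundaries or composition, no
temporal mismatch between survey and imagery, and its bias mechanism is a
single smooth elevation displacement rather than the patchwork of
historical land-use decisions. The improvement margin also varies with the
landscape draw — where the suitability surface is diffuse, the area-only
selection spreads widely and already intersects most sites, leaving the
filter little headroom.

## Numerical conventions and degenerate inputs

Probability ties in ranking break by (row, col); threshold ties break to
the smallest threshold; largest-remainder rounding is used wherever integer
counts must preserve a total (compositions, quota rescaling). Selections
report shortfalls instead of silently reallocating. Empty training sets,
one-class splits, off-grid training pixels, negative quotas or targets, and
empty site lists raise immediately with named errors. All randomness flows
from integer seeds through `numpy.random.SeedSequence`; re-running any
stage with the same configuration reproduces every artifact byte-for-byte
(learner fits included — estimators are seeded and single-threaded).

## Problem sizes

Default analysis runs use a 160 × 240 grid (12 × 8 km at 50 m, ~540
stands) with three regions and 5 cross-validation repeats per replicate;
the package default for `n_repeats` is 30, matching the study design the
pipeline implements. The test suite exercises the full 4 × 15 × 30 ledger
on a 100 × 100 single-region landscape and the end-to-end bias comparison
on 100 × 150.

## Known limitations

* Stand shapes from the serpentine tessellation are banded rather than
  naturalistic; their area and adjacency statistics, which are what the
  pipeline consumes, are realistic.
* The elevation filter treats the quota histogram as exact; survey noise in
  the histogram propagates directly into the selection.
* Coincidence uses the any-overlap rule; a majority-overlap rule would be
  stricter and is not implemented.
* No spatial cross-validation: train/test splits are random over pixels, so
  reported TSS includes the optimism that spatial autocorrelation lends any
  non-spatial split. The real-data analogue shares this property.
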