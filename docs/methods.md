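# Methods

This note documents the models, conventions, and numerical choices behind
`ensdm`, and what the synthetic-data validation does and does not
demonstrate.

## Spatial conventions

All rasters live on a regular longitude/latitude lattice (default 0.1°),
cell-center registered, row 0 = northernmost row, on a spherical datum with
R = 6371 km (no published datum choice binds this workflow; the constant is
`ensdm.grids.EARTH_RADIUS_KM`). Point-to-cell assignment is half-open,
`[edge, edge + resolution)` measured from the north-west corner, so a point
on a shared edge belongs to exactly one cell — one stated convention
eliminates off-by-one disputes at boundaries. Cell areas use the exact
spherical-zone formula `R²·Δλ·(sin φ_top − sin φ_bot)`; a full-longitude
band therefore sums to `2πR²(sin φ₂ − sin φ₁)` to rounding error, which the
tests assert at 1e−6 relative tolerance.

Resampling between grids samples at target cell centers: bilinear for
continuous fields (exact on affine fields, verified), nearest-neighbor for
masks and categorical layers, where interpolating between category codes is
ill-defined. Fractional land-use layers are clipped back to [0, 100] after
resampling because bilinear interpolation can overshoot at sharp edges.
Missingness propagates conservatively: a stack cell is valid only where
*every* layer has data, and any interpolation touching a nodata source cell
yields nodata.

GeoTIFF I/O writes single-band float32 with the standard georeferencing
tags (pixel scale, NW-corner tie point, a GeoKey directory declaring
geographic WGS84, GDAL nodata = −9999); files without georeferencing are
rejected rather than silently assigned a grid.

## Occurrence processing

Cleaning collapses exact duplicates (species + coordinates), drops records
outside the study extent or off the land mask, and applies a temporal
window (default 2014–2024, matching the contemporary-distribution premise
of the predictors). Every stage's removal count is reported.

Spatial thinning keeps one record per 1 km × 1 km cell of a local metric
grid (longitude scaled by cos latitude — indistinguishable from a projected
grid at this scale). The retained record is the lexicographic minimum of
(year, lon, lat): a deterministic, seed-free tie-break chosen over the
stochastic thinning common in the field because it makes thinning
idempotent and exactly reproducible; the cost is a fixed (rather than
randomized) preference among near-duplicates, immaterial at 1-km scale.

Pseudo-absences are drawn at *cell* level — models are fit on cell-level
predictor values, so sub-cell placement would add no information — uniformly
without replacement from the accessible area: the full valid domain for
inland taxa, or cells whose centers lie within a great-circle distance
(default 200 km) of the coastline for coastal taxa. Presence cells are
excluded from the background to prevent contradictory labels. The count is
exactly `ratio × n_presences` (default 2:1 absence:presence); a shortfall is
an error naming the deficit, never a silent under-sample.

## Member models

**MaxEnt-style.** The presence/background formulation is fit as an
L1-penalized logistic regression (scikit-learn liblinear, tolerance 1e−8)
on the expanded feature basis: per predictor, linear + quadratic + 10
forward and 10 reverse hinge features with equally spaced knots, plus all
pairwise products — 175 columns for 7 predictors — every feature min-max
scaled to [0, 1] using bounds frozen from the training table (prediction
inputs are clamped to those bounds, the usual clamping behavior for
extrapolated projection). A fixed knot count is used instead of data-driven
knot placement for determinism. The inverse-penalty C is selected from a
small grid (0.01, 0.1, 1, 10) by held-out log-likelihood on an internal
stratified 80/20 split. The linear predictor maps to suitability by
cloglog, `s = 1 − exp(−exp(η + c))`, with `c` chosen so the *mean presence*
linear predictor maps to τ = 0.5 (configurable) — the standard convention
anchoring cloglog output to a typical-presence probability of one half.

**Random forest.** 500 classification trees, `mtry = ⌊√p⌋ = 2` candidate
predictors per split for the 7-layer stack, suitability = averaged class
probability (smoother surfaces than majority vote), fixed seed.

Both models serialize and reload with bitwise-identical predictions, and
project over a stack in bounded-memory row blocks.

## Evaluation, gating, thresholds

Stratified k-fold (default 5) assigns each class round-robin after a seeded
shuffle, so per-class fold counts differ by at most one. AUC is computed
from average ranks (ties count one half) and is verified against an O(n²)
pairwise oracle; TSS maximizes Youden's J over candidate thresholds at
midpoints between consecutive distinct scores (±∞ included), ties broken
toward the lower — more sensitive — threshold. Fold summaries report mean ±
sample SD (denominator k − 1).

Ensemble gating applies AUC ≥ 0.90 and TSS ≥ 0.70 *inclusively* to the CV
means; weights are AUC-proportional and sum to one.

**P10.** The threshold is the linearly interpolated 10th percentile of
predicted suitability at the calibration presences, capped at the largest
order statistic that still keeps ≥ 90 % of those values at or above the
threshold. The cap matters: for some sample sizes (e.g., n = 25 distinct
values) the plain interpolated quantile retains only 88 % of presences, and
the ≥ 90 % coverage guarantee is the threshold's defining contract. Member
P10s come from each member's own presence predictions; the ensemble P10 is
recomputed from the weighted ensemble predictions at the same presences.
Below 10 presence values the rule degrades to the empirical minimum with a
warning. Binarization is inclusive (`suitability ≥ threshold` → suitable).

## Projection and area accounting

Scenario stacks are projected through the fitted ensemble unchanged. Binary
maps for future scenarios reuse the **baseline** ensemble P10 by default —
the threshold is a property of the calibration presences, which have no
future analog — with per-scenario recomputation available by flag.
Summaries (mean, median, 95th percentile, all via the interpolated-quantile
convention) are taken over valid cells of the modeling domain. Areas above
fixed thresholds (0.3/0.5/0.7) and above P10 use the geodesic cell-area
raster; the four-class change map (stable-suitable / gain / loss /
stable-unsuitable) satisfies `area(gain) − area(loss) = Δarea` exactly, an
accounting identity asserted in the tests.

## Interpretation

Permutation importance averages the AUC drop over 10 column shuffles
(repetition count configurable; seed-derived permutations). Shapley values
are computed by **exact enumeration** of all 2⁷ coalitions, marginalizing
withheld predictors over a background sample — at p = 7 this is cheap and
strictly dominates sampling estimators, making local accuracy (base +
contributions = prediction) exact; a Monte-Carlo permutation estimator is
retained for larger predictor sets and is cross-checked against the exact
one. Mean |SHAP| effect classes use inclusive lower bounds: ≥ 0.05 strong,
[0.02, 0.05) moderate, < 0.02 weak. Partial dependence holds co-predictors
at their medians by default (means by option). VIF is 1/(1 − R²) from
least-squares regression of each predictor on the others; perfect
collinearity reports as infinity.

## The synthetic landscape and what passing tests show

The generator emulates the *structure* of a continental SDM input, not any
real place: BIO1 is a latitudinal gradient plus a smoothed Gaussian random
field (kernel-smoothed white noise — simple, dependency-light, seed-stable);
BIO4/BIO12/BIO15 are independent smoothed fields at realistic magnitudes;
Urban/Crop/Pasture are logistic-squashed fields in percent, with urban
intensity decaying away from a meandering eastern coastline; sea cells are
masked in all layers. The default grid is 100 × 100 at 0.1° so every stage
runs in seconds; problem sizes in tests and the acceptance script (300 and
150 presences, 1:2 backgrounds, 5-fold CV, 500 trees) were chosen to keep a
full run around half a minute on one core while preserving the study
design's proportions.

Virtual species combine per-predictor response curves (Gaussian, logistic,
or linear ramp) by product or geometric mean. Presences are sampled
*proportionally to true suitability* — a simple model of opportunistic,
abundance-weighted recording — with within-cell jitter and years uniform in
2014–2024. The default species are deliberately **strong-signal
specialists**: the inland taxon occupies a narrow warm–wet, low-agriculture
envelope and the coastal taxon a narrow thermal band on the urbanized
coastal fringe. This calibration reflects the operating regime the pipeline
is designed for — taxa coherent enough that both members clear the
performance gate (the fitted members reach cross-validated AUC ≈ 0.93–0.98
across seeds) — and it is what makes ground-truth recovery a meaningful
test: the ensemble surface correlates with true suitability at Spearman
ρ ≥ 0.7 for the inland species at the tested seeds. The coastal species'
ρ is lower and more variable because most of its domain is near-zero
suitability, where ranks are dominated by noise.

Scenario perturbations are affine (a temperature offset, a precipitation
scale factor, additive land-use trends re-clipped to [0, 100]). They
exercise the projection machinery and reproduce the qualitative signature
of interest — continuous mean/median suitability can rise while the
P10-thresholded area contracts — but they are not climate-model output and
carry no spatial pattern of a real scenario.

What passing tests therefore show: the pipeline's algebra, conventions, and
code paths are correct, and the workflow recovers a known truth under its
own sampling model. What they do not show: robustness to sampling bias
beyond suitability-proportional detection, taxonomic error, predictor
misspecification, or the spatial complexity of real climate and land-use
change.

## Degenerate inputs and tie rules (summary)

- Constant predictors: quadratic/hinge features dropped with a warning.
- Single-class labels: error, for fitting and for every metric.
- Nearest-neighbor ties at exactly half a cell: resolved toward the lower
  coordinate (scipy's convention), documented in the resampler.
- Youden ties: lowest threshold (highest sensitivity).
- Thinning ties: lexicographic (year, lon, lat) minimum.
- Empty gate survivors: error carrying the full metric table.
- Fewer than 10 presences for P10: empirical minimum, with a warning.

## Known limitations

- No projected-CRS support; geographic lattices only.
- No spatially blocked cross-validation (random stratified folds can be
  optimistic under strong spatial autocorrelation).
- The MaxEnt-style model fixes the regularization search to a small grid
  rather than reproducing maxnet's feature-class-dependent multiplier
  tables.
- Pseudo-absence design is uniform within the accessible area; no
  target-group or bias-file weighting.
- Family-level (guild-level) modeling semantics are inherited from the
  inputs; nothing in the code resolves taxonomy.
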