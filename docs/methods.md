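# Methods

## The q-statistic (factor detector)

For a numeric variable *y* observed at *N* locations stratified into *L*
strata (here: vegetation classes), the q-statistic is

q = 1 − (Σ<sub>h=1..L</sub> N<sub>h</sub> σ<sub>h</sub>²) / (N σ²)

with **population** variances (denominators N<sub>h</sub> and N), so q
reduces exactly to 1 − SSW/SST — one-way-ANOVA eta-squared. Sample
(N−1-denominator) variances would make the statistic depend on stratum
sizes in a way inconsistent with the variance-decomposition identity, so
they are not used. Edge rules: SST = 0 (constant *y*) returns q = 0 — a
constant covariate explains nothing and is not an error; floating-point
negatives are clamped to 0; q requires L ≥ 2 strata each with at least one
sample. q = 1 exactly when every stratum is internally constant.

Significance is assessed with a one-sided Monte-Carlo permutation test:
stratum labels are shuffled uniformly B times and
p = (1 + #{q<sub>perm</sub> ≥ q<sub>obs</sub>}) / (B + 1). The +1 terms keep
p valid (never 0) and the test exact up to Monte-Carlo error; on tiny
samples it can be checked against exhaustive enumeration of all label
arrangements. A permutation test was chosen over the noncentral-F
approximation because it is assumption-free and directly verifiable.
`q_table` accepts B = 0 to skip the test when only the q ranking is needed.

Caveat: label permutation assumes exchangeability, which spatial
autocorrelation violates — with thousands of autocorrelated pixels even a
tiny q can be "significant". Screening therefore rests on the q magnitude
threshold, with p-values reported as supporting context only.

## Index selection

Per vegetation pair, variables with q strictly greater than a threshold
(default 0.3, a conventional benchmark for a meaningful climatic-zone
stratification) are kept, sorted by descending q, truncated to the top k
(default 4, which equalizes the feature count across pairs). Ties break by
ascending variable name so selection is a pure function of the q column.
If fewer than k variables pass, the shorter system is returned with a
warning rather than padded — padding would violate the threshold rule.
Note: published screening tables in this setting can disagree with their
accompanying text about how many variables clear 0.3; this implementation
follows the numbers it is given.

## Zonation

A support-vector classifier (RBF kernel by default, C = 1, gamma =
1/(n_features · var), z-score standardization, inverse-frequency class
weights) is trained on the labelled pixels' index-system values and
applied to every non-masked pixel. Kernel, C, gamma and standardization
are exposed in `ZonerConfig` because the boundary position is sensitive to
them; class weighting matters because the two vegetation types rarely
cover equal areas. Training reports resubstitution accuracy only — with
wall-to-wall prediction there is no held-out spatial unit, and boundary
recovery is instead validated against synthetic truth. Prediction streams
in row blocks; the block size cannot affect the output.

## Boundary extraction and transition composition

The boundary of a two-zone map is the set of pixel edges shared by a
0-pixel and a 1-pixel under 4-connectivity (8-connectivity would make
diagonal pairs ambiguous). Unit edge segments are chained into maximal
polylines (`shapely.ops.linemerge`); masked pixels contribute no edges.
Boundary length is the segment count times the cell size.

Several pairs' boundaries are composed column-wise (west → east, matching
an east-west-elongated study area — a documented limitation where a
boundary runs locally north-south): per column, the northernmost and
southernmost crossings of the column's centre line over all boundary sets
bound the band, **inclusive**, so coincident boundaries yield a one-pixel
band and the three-zone partition always exists. Columns crossed by no
boundary inherit the nearest crossed column's envelopes and are excluded
from the mean width. Pixels north of the band are temperate, south of it
subtropical; the partition is disjoint and exhaustive over non-masked
pixels by construction and machine-checked in tests. Width is the
north-south extent per column, converted to km via `km_per_cell`
(default cell_size/1000, i.e. metre grids; great-circle corrections are
ignored — below 0.2% error at 1-km cells in mid-latitudes).

For scoring recovery, `boundary_median_rows` summarizes a boundary as its
per-column **median** crossing row: the median is robust to the occasional
isolated misclassified pixel far from the true boundary, which would
otherwise dominate an envelope-based position estimate.

## Characterization and validation

`sample_zones` draws a fixed number of pixels per zone uniformly
**without replacement** (with replacement would double-count pixels); a
zone smaller than the request is taken in full with a warning, and a full
census is seed-independent. Per index, the zone table reports per-zone
sample means in raw covariate units and a three-stratum q on the pooled
sample. The default 500 samples per zone reflects the reference analysis
design (500 read as per-zone, since per-zone means are reported).

Quadrat validation grades stem counts into low/moderate/high per indicator
species using inclusive intervals (subtropical indicators 2–3 / 4–10 /
11–98; the temperate indicator 2–10 / 11–20 / 21–60); counts outside all
bins are ungraded and excluded. Each graded quadrat is assigned the zone
of its containing pixel; a subtropical indicator is *consistent* when it
falls in the subtropical or transition zone, a temperate indicator in the
temperate or transition zone. Consistency is reported descriptively as
per-species fractions, not tested inferentially — it is a plausibility
check, not a hypothesis test.

## Synthetic landscapes

The generator emulates the structure of a mountain climate divide, not any
real region's values:

- **Driver covariates** (default `meantem01`, `pa`, `tadem`, `aat0`) share
  one north-south profile: a logistic ramp of range 10 covariate units
  centred on the divide (the mean of the pair boundary rows; steepness 5%
  of grid rows) with i.i.d. Gaussian measurement noise, sd 0.3 units.
  The sigmoid — plateaus on each side of a steep ramp — is what makes the
  divide a divide; a linear ramp would cap q at 0.75 for a midpoint split
  and could never exhibit the near-complete stratified heterogeneity that
  real zonal climate variables show. An optional Gaussian ridge term can
  be added to the last driver to emulate elevation.
- **Nuisance covariates** (soil-like) are spatially autocorrelated
  Gaussian fields (correlation length 5 cells) independent of vegetation —
  autocorrelation makes their spurious q realistically non-zero, genuinely
  stressing the 0.3 threshold. At the reference 200×200 scale their q
  stays ≈ 0.01–0.03; on very small grids (few independent patches) it can
  reach ~0.2 by chance.
- **Vegetation**: per pair, a pixel is temperate north of the pair's
  boundary row (flat by default; optionally sinusoidally bent), subtropical
  south of it, and actually labelled with probability `occupancy_rate`
  (default 0.15) — vegetation polygons never tile a whole climate zone.
  Default boundaries for the three pairs are rows 85/100/115 on a 200×200
  grid of 1-km cells, i.e. a true 31-row transition band with pair offsets
  of 15 cells, mirroring the observation that coniferous and broad-leaved
  range limits differ slightly.
- **Quadrats**: uniform locations; counts are Poisson with mean 30 on the
  species' own side of its pair's boundary, decaying with an e-folding of
  4 cells past it.

What the generator does **not** emulate: realistic absolute climate units,
anisotropic terrain effects, spatial autocorrelation in the *driver* noise,
label errors in the vegetation map, and boundaries controlled by more than
one independent covariate axis. Passing recovery tests therefore shows the
workflow is correct and well-behaved under its stated assumptions, not that
it is robust to every failure mode of real survey data.

Because a single shared monotone field cannot be internally constant on
both sides of three different boundary rows at once, the noiseless
"driver q ≈ 1" property holds exactly for a pair at the divide; pairs
offset by 15 cells score q ≈ 0.83–0.85, still far above the selection
threshold.

## Problem sizes and numerical choices

Reference experiments use 200×200 grids (40,000 pixels, ~6,000 training
pixels per pair at 15% occupancy), 10 replicate seeds for the width
experiment and 100 landscapes for the ranking experiment — sizes at which
the recovery statistics are stable while a full run stays in the tens of
seconds. Geometry comparisons use 1e-9 absolute tolerance; grids are
north-up, row 0 = north, pixel coordinates are cell centres;
rasterization uses the pixel-centre containment rule, and a pixel claimed
by both classes of a pair is excluded (-1) to avoid label noise. No
reprojection is performed anywhere: layers must share a CRS tag.

## Known limitations

- Column-wise envelopes assume a predominantly east-west transition band.
- The composed band uses extreme crossings, so it is conservatively wide
  in the presence of classification speckle (the measured synthetic widths
  run ~0–3% above truth under the reference noise).
- Only static, single-epoch regionalization; no probability calibration or
  hyperparameter search for the classifier.
- ASCII-grid raster I/O assumes square cells and a single band per file.
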