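# Methods

## Problem and model

`landfuse` maps three land-use classes — arable land in use (1), abandoned
arable land (2), other land (3) — by fusing K existing land-cover/land-use
rasters that disagree with each other, use different legends and resolutions,
and may each cover only part of the region. The fusion model is a Naive
Bayes classifier over the source readings: for a cell with true class G and
source readings S_1..S_K,

    Pr(G = g | S_1..S_K) = Pr(g) Π_k Pr(S_k | g) / Σ_g' Pr(g') Π_k Pr(S_k | g'),

i.e. each source is treated as a conditionally independent witness of the
truth. Sources need not share a legend: each factor Pr(S_k | g) is read from
that source's own conditional table. A source with no coverage at a cell
contributes no factor; because conditional rows sum to one, omitting the
factor is exactly marginalizing the joint over that source's possible
readings (verified numerically in the test suite against brute-force joint
enumeration). The final map is the per-cell argmax of the posterior, ties
broken toward the smallest class code.

Each input source is its own conditionally independent factor (plain Naive
Bayes). The general formulation allows grouping sources into joint subsets,
but no grouping is specified for any input we model, and the plain
factorization is what the per-cell worked arithmetic uses.

## Conditional tables and stratification

Conditional tables Pr(S_k = c | G = g) are estimated from contingency tables
of point reference labels (visual interpretations) against each source map.
Estimation is stratified by an ecozone-style raster: the land cover that
follows abandonment differs between, say, forest and steppe zones, so each
stratum gets its own tables. Details:

* "Not sure" reference points are excluded from training.
* A point where source k has no coverage contributes nothing to source k's
  table (but still counts for the other sources).
* Additive smoothing `s` gives Pr(c|g) = (n_gc + s) / (n_g. + s·|A_k|).
  Default s = 0: raw contingency proportions, including exact zeros, which
  is what the per-cell worked arithmetic assumes. Turn on s > 0 when zero
  cells produce degenerate posteriors.
* A (stratum, source) table with total support below `min_support`
  (default 30 points — contingency proportions on fewer observations are
  too unstable to stratify on) is replaced by the pooled all-strata table
  and flagged.
* A single empty row (a truth class never observed for that stratum/source)
  inside an otherwise well-supported table falls back to the pooled row for
  that class, then to uniform if the pooled row is empty too. This keeps
  every row a probability distribution without forcing smoothing on.
* Cells where the product assigns zero likelihood to all three classes fall
  back to the prior and are flagged in a diagnostic plane rather than
  becoming silent NaNs.

Priors default to exactly (1/3, 1/3, 1/3); they cancel in the posterior
ratio for any equal prior. Region-specific priors can be supplied.

## Harmonization conventions

All rasters are geographic WGS84 on a common target grid (the production
target is 10 arc-seconds, anchored at integer multiples of the cell size
from (-180°, +90°)). Rows run north to south; indices are 0-based; cell
extents are half-open, so a point on a shared edge belongs to the cell to
its south-east (a 1e-9-cell forward nudge in the point-in-cell arithmetic
makes this hold under floating-point rounding).

* **Legend simplification** is a many-to-one code mapping per source, with a
  configurable policy (strict / pass-through / to-nodata) for unmapped codes.
* **Aggregation** (finer source → target): categorical by majority vote,
  continuous by arithmetic mean. A source cell contributes to the target
  cell containing its center; no area weighting. Majority ties break to the
  smallest class code. Nodata cells do not vote, and a target cell becomes
  nodata when more than half its contributors are nodata.
* **Nearest-neighbour resampling** assigns each target cell the value of the
  source cell containing its center; cells outside the source footprint
  become nodata.
* **Thresholding** converts percentage layers to presence/absence with
  `value >= threshold` (default 50%). The ≥ convention is fixed and
  documented: the boundary value counts as present.

## Validation and area estimation

The validation design is two-step stratified random sampling: first by
region, then by mapped class, with simple random sampling without
replacement inside each (region, mapped class) stratum, allowing rare
classes (arable, abandoned) to be oversampled.

Reference labels may be ambiguous ("not sure between X and Y", codes 12, 13,
23). An ambiguous record adds 0.5 to each of the two candidate reference
columns of the confusion matrix; an unambiguous one adds 1.0, so the matrix
mass always equals the number of scored records but cells are real-valued.

Accuracy and area estimates use the stratified estimators for a sample
stratified by mapped class. With W_i the mapped-class area proportions
(computed from the fused map within the region, nodata excluded) and
p_ij = W_i n_ij / n_i.:

* overall accuracy Σ_i p_ii, user's accuracy n_ii/n_i., producer's accuracy
  p_jj / Σ_i p_ij;
* error-adjusted proportion of class j is the column total Σ_i p_ij, and the
  adjusted area is that proportion times the region's total area;
* variances are the standard stratified estimators, with the fractional
  n_ij entering as real numbers — the natural plug-in extension, since the
  sampling design is unchanged; the "±" reported everywhere is a 95%
  half-width (1.96·SE), with raw SEs exposed alongside.

Monte-Carlo checks in the test suite confirm ~95% coverage of the area CIs
over 1,000 simulated validation samples from a known error matrix.

`change_summary` is a generic two-epoch summarizer: loss and gain of a class
as percentages of the class extent at the first epoch (falling back to the
total co-mapped area when that extent is zero).

## Synthetic scenes

The generator produces fully seeded scenes with the statistical structure
the pipeline assumes:

* **Truth**: Gaussian-smoothed white noise (σ = `patch_scale`, default 6
  cells) rank-mapped to classes within each stratum, so realized per-stratum
  class proportions equal the configured ones to within one cell. Strata are
  contiguous vertical bands — ecozone realism is irrelevant to correctness
  testing.
* **Sources**: each cell's reading drawn independently from the confusion
  row of its truth class in its stratum; partial footprints are seeded
  unions of random rectangles hitting the coverage fraction within ±5%
  (each rectangle ≈2% of the grid, bounding the overshoot). Continuous
  sources emit 100·1{reading = cropland-like} blurred with Gaussian noise
  (default 10 percentage points) and clipped to [0, 100].
* **Samples**: reference points are an SRS of cells labelled from the truth,
  with a configurable "not sure" rate (default 5%) and label-noise rate
  (default 0); validation records are drawn from cells disjoint from the
  reference cells, with ambiguity expressed as paired codes (12/13/23)
  combining the true class with a uniformly chosen other class.

Default study conditions: 300×300 grid, 3 strata, per-stratum class
proportions (0.30, 0.20, 0.50), four 3-class sources with diagonal
accuracies 0.85/0.80/0.75/0.70 and full coverage, 5,000 reference and 1,500
validation points, seed 42. These sizes keep the full suite and the
acceptance script in seconds while leaving per-table support in the
hundreds of points.

What passing on synthetic scenes does **not** show: sources generated this
way are exactly conditionally independent given the truth, which real map
products are not (they share sensors, training data and epochs); reference
labels here are noise-free draws from the truth, while real interpreters
disagree systematically; and the landscape model has no succession dynamics
or georeferencing error. An optional correlated-pair mode is deliberately
out of scope of the defaults; violation of the independence assumption
inflates posterior confidence before it degrades the argmax map.

## Statistical resolution of parameter recovery

With R reference points spread over E strata and class proportions π_g, a
(stratum, truth-class) contingency row receives about R(1−r_ns)π_g/E points
(r_ns the "not sure" rate). Each fitted entry is a multinomial proportion
with SE ≈ sqrt(p(1−p)/n_row); under the default conditions rows hold
~300–550 points, so entries carry SEs up to ~0.02 and the worst of the ~108
estimated entries is expected ~3 SE ≈ 0.05–0.06 from its generator. The
end-to-end test therefore checks each entry against its own 4-SE band
rather than a single absolute tolerance; an absolute 0.03 band would need
roughly 10,000 points per stratum (as the dedicated large-sample recovery
test uses for its 0.02 tolerance at a single stratum).

## Numerical choices

* Posterior products are computed in plain float64 (no log-space): with at
  most tens of sources and probabilities ≥ machine-epsilon scale, underflow
  is not reachable before the zero-likelihood fallback triggers.
* All tie-breaks (argmax, majority, edge ownership) are deterministic and
  order-independent; permuting the source list leaves posteriors unchanged
  to 1e-12.
* Every stochastic operation takes an explicit seed (default 42); scene
  generation derives per-source seeds from a seed sequence so adding a
  source does not reshuffle the others.
* GeoTIFF I/O writes the standard georeferencing tags (ModelPixelScale,
  ModelTiepoint, GeoKeyDirectory declaring EPSG:4326, GDAL nodata) on
  single-band files; categorical rasters are int32, continuous float64.
  Reprojection between CRSs is out of scope — all inputs are assumed
  geographic WGS84.

## Known limitations

* Only the plain Naive Bayes factorization is implemented; inter-source
  dependence is neither learned nor modelled.
* No temporal model of the abandonment process; epochs enter only through
  which sources are supplied.
* `allocate_sample` requires the caller to supply per-(region, class)
  sizes; it does not compute an optimal allocation.
* Anisotropic cells and multi-band source files are unsupported by design.
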