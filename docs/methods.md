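# Methods

This note documents the models and procedures implemented in `plateausdm`,
the choices made where the design was genuinely open, and what the synthetic
landscape does and does not establish about real data.

## Study system and workflow

The package reproduces, at desk scale, an integrated predator–prey habitat
analysis for the Tibetan brown bear and its two principal prey species
(Himalayan marmot, plateau pika) on the Qinghai–Tibet Plateau. The stages
are, in order: spatial thinning of occurrence records; collinearity
screening of the environmental layers; per-species presence-background
maximum-entropy modelling with replicated evaluation; binarization of the
replicate-mean suitability at the replicate-mean MTSPS threshold; consensus
intersection of future binary maps across climate-model variants; and a
three-way overlay (S1 ideal range / S2 stepping stone / S3 potential
conflict zone) with zonal area, percent-change and centroid-shift tables.

## Grids and I/O

All spatial data are square-cell grids with a single nodata mask
(`GridRaster`); a scenario's environment is a name-keyed, geometry-validated
set of layers (`RasterStack`) whose combined valid mask is the cell-wise AND
of the per-layer masks. No resampling or reprojection is implemented:
inputs must already share geometry, mirroring a workflow in which alignment
happened upstream in GIS tooling. Rasters are written as minimal
single-band GeoTIFFs through `tifffile`, carrying pixel scale, top-left
tiepoint, a CRS label and the nodata sentinel as standard tags; float
rasters round-trip exactly (float64), integer rasters bit-identically.
Points map to cells under half-open intervals ([left, right) in x,
(bottom, top] in y), so every point belongs to exactly one cell.

## Occurrence thinning

Occurrences are binned on a coarse grid anchored at the raster origin
(default cell side 10 km — the conventional reading of a "10-km grid"
filter; cells of literal area 10 km² would have side ≈ 3.16 km) and one
point per occupied bin is kept, chosen uniformly under the stage seed. The
retained count is therefore seed-invariant, thinning is idempotent, and
anchoring to the raster origin (not the data extent) makes results
comparable across species.

## Collinearity screening

Pairwise Pearson correlations are computed among continuous layers over the
combined valid mask only. Variables are then eliminated greedily: while any
remaining pair has |r| above the cutoff (default 0.7), the variable with
the largest mean absolute correlation to the other remaining variables is
dropped, ties broken by reverse lexical order. The greedy rule is one
deterministic, auditable choice among several defensible ones; it can keep
one variable fewer than the exhaustive maximal valid subset on adversarial
matrices, which the tests document. Zero-variance layers have undefined
correlations and are dropped first. Categorical land cover bypasses
Pearson screening entirely (correlation on class codes is meaningless) and
is always kept.

## Maximum-entropy engine

**Model.** The fitted object is the Gibbs distribution q(x) ∝ exp(Σ λ_f
f(x)) over the training landscape (the union of presence cells and a
uniform background sample, default 10,000 cells — the customary default,
as the background count is rarely reported). Features per continuous
variable: linear, quadratic, all pairwise products, and forward/reverse
hinges with knots at the deciles (10%…90%) of the variable over the
stack's valid cells; categorical variables contribute one indicator per
observed class. Every feature is min–max scaled to [0, 1] on the training
stack and clamped back into [0, 1] when projected onto new scenarios, so
projections never extrapolate beyond the trained range.

**Penalty.** β_f = multiplier × base(class, m) × s_f / √m, where base is
the per-feature-class value interpolated at the presence count m from the
standard tables (linear/quadratic/product: (0, 10, 30, 100) → (1.0, 1.0,
0.2, 0.05); categorical: (0, 10, 17) → (0.65, 0.5, 0.25); hinge: constant
0.5) and s_f is the standard deviation of the feature over the presence
sites, floored at 0.05 so features nearly constant on presences keep a
non-degenerate penalty instead of an unbounded coefficient.

**Optimizer.** Cyclic coordinate descent. Along one coordinate the
penalized gain is concave, so a bounded scalar search (|λ| ≤ 60, xatol
1e-7) finds the 1-D optimum exactly; a zero coefficient whose gradient
magnitude is within its penalty is provably optimal and skipped. Only
improving steps are accepted, making the per-cycle gain trace
non-decreasing by construction. Convergence is a full cycle improving the
gain by less than `convergence_tol` (default 1e-5); hitting
`max_iterations` (default 500 cycles) returns the best iterate flagged as
unconverged. Gain increments are credited to the updated feature's source
variable (split evenly for products); clipped-at-zero, normalized credits
are the percent-contribution table.

**Outputs.** Raw output exp(η)/Z sums to 1 over the training landscape
(asserted to 1e-6). Logistic output p = τ e^H q/(1 − τ + τ e^H q) with
τ = 0.5 and H the entropy of q; for the uniform model (λ = 0) this is
exactly τ everywhere. AUC is the rank statistic P(presence outscores
background) with ties at 0.5.

**Replicates.** Default 15 replicates of a 75/25 random presence split
(at least one test point). The protocol names both a "random test
percentage of 25%" and "cross-validation"; repeated random subsampling
honours the explicit 25% figure and is the implemented default. Each
replicate's MTSPS threshold is computed on its *training* presences
against the shared background; the final suitability map is the cell-wise
replicate mean and the final threshold the replicate-mean MTSPS.

## Binarization and consensus

A cell is suitable iff its suitability ≥ threshold. The boundary is
inclusive because the MTSPS threshold is itself an observed score; with ≥,
sensitivity 1 remains attainable and the maximizing candidate keeps its
own presence suitable. Ties in the MTSPS objective resolve to the lowest
candidate (with a 1e-12 tolerance absorbing floating-point noise between
algebraically equal forms). Future scenarios binarize each climate-model
variant first and intersect afterwards: a cell counts as future-suitable
only if every variant agrees.

## Overlay and statistics

With bear range B and prey layer P (default rule: union of marmot and pika
ranges, since conflict is framed as arising where prey is absent — either
prey species suffices; "both" is available as a config option): S1 = B∧P,
S2 = ¬B∧P, S3 = B∧¬P, NONE otherwise. The identities |S1|+|S3| = |B| and
|S1|+|S2| = |P| hold exactly and are asserted. Areas are cell counts times
the nominal cell area (1 km² default; geodesic correction is out of
scope). Percent changes are 100·(future − baseline)/baseline and regional
proportions 100·region/total, both rounded half-up to two decimals to match
conventional table formatting. Range centroids are unweighted means of
suitable-cell centers; shifts report Euclidean distance and compass bearing
(clockwise from north; a zero-length shift reports bearing 0, flagged).

The published regional and overlay-class area tables for the real study
system are embedded in `plateausdm.datasets`; feeding them through the same
change/proportion arithmetic reproduces the reported headline statistics
(e.g. a 16.78% bear-range decline under RCP4.5, a 21.92% S1 contraction
and 17.03% S3 expansion, 44.47%/89.39% pika declines in Sichuan/Yunnan,
a 60.64% Xizang share of the RCP8.5 bear range). Note the published S1+S3
total exceeds the bear-range total from the regional table, so the
reported class areas cannot be the literal partition this package computes
on one landscape; the overlay here implements the class definitions
literally and asserts its own internal identities instead.

## Synthetic landscape

Continuous layers are Gaussian-smoothed white noise (autocorrelation range
in cells), standardized exactly to mean 0, sd 1 over valid cells; land
cover is a smoothed field quantile-binned into 3–6 classes; regions are
nearest-seed (Voronoi, hence contiguous) partitions. The generative truth
is an inverse-logit of linear and quadratic terms plus per-class offsets,
optionally intercept-shifted to hit a prevalence target; occurrences sample
cells proportionally to truth with a uniform point inside each cell.
Future scenarios shift/scale continuous layers, add per-variant Gaussian
noise (the "climate-model" disagreement the consensus stage exercises),
reassign a fixed fraction of land-cover cells to a degraded class, and copy
elevation and human influence unchanged (assumed constant over time).

The default end-to-end design uses a 150 × 150 grid of nominal 1-km cells,
raw occurrence counts matching the field survey (585/308/311), 10-km
thinning, three scenarios × three variants, and six regions. Problem sizes
throughout (grid side 30–150, background 500–10,000, 3–15 replicates) are
the package's own desk-scale choices, selected so a full run completes in
minutes on one CPU.

**What passing tests show — and don't.** The synthetic landscape has
independent, stationary, Gaussian-ish layers, a correctly specified
logistic truth, and no sampling bias, so parameter-direction recovery and
AUC benchmarks here are best-case results; real occurrence data bring
spatially biased effort, measurement error, non-stationarity and
misspecification that these tests do not probe. Two desk-scale artifacts
deserve mention: 10-km thinning on a ~100-km domain leaves at most a few
hundred thinning bins, flattening the spatial distribution of presences and
depressing test AUC relative to what the same engine achieves on large
domains; and with all layers generated independently, the collinearity
screen usually retains all eight variables (engineered correlated stacks
are used to exercise elimination).

## Numerical choices and degenerate inputs

Seeds derive from the master seed by SHA-256 over a tag path (stage /
species / replicate), keeping streams independent and every output
reproducible byte-for-byte. Degenerate cases are defined rather than left
to chance: all-equal scores give MTSPS = that score; an empty class yields
no zonal rows (not a division by zero); zero total gain splits
contributions uniformly with a flag; an all-nodata raster reads back with
an empty valid set and a log line; constant variables contribute no
features. Known limitations: no geodesic areas, no reprojection, no
distance-based thinning, single-algorithm SDM (no ensembles), and hinge
(not threshold) features only.
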