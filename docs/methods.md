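# Methods

## Scope and data model

All analysis happens on planar single-band rasters (`Grid`): a value
matrix, an affine georeference (top-left origin, positive cell sizes, row 0
northernmost), a boolean validity mask (`False` = land/nodata) and a cell
area in km². Coordinates are kilometres; equal-area cells are assumed
throughout and a `crs_tag` is carried opaquely — no reprojection is
performed, so area figures are exact cell counts times cell area. Point
membership in cells uses half-open intervals `[x0, x0+w) × (y0−h, y0]` so
boundary points are assigned deterministically. Nodata propagates: every
stage's output mask is the intersection of its input masks.

GeoTIFF I/O is built on `tifffile` with the standard georeference tags
(ModelPixelScale, ModelTiepoint, GDAL nodata); ESRI ASCII grids are parsed
directly. Polygons travel as GeoJSON via `shapely`; point tables as CSV
with columns `x, y, date, season, count, source`.

## Occurrence preparation

Occurrences are spatially rarefied to at most one record per analysis-grid
cell (the analysis resolution, 1 km in the default scenario), the retained
record chosen uniformly at random under a seed; rarefaction is idempotent.
Records are split into site-specific monsoon seasons by an explicit month →
season map (the bundled island calendar: Jan–Apr pre-monsoon, May–Sep
monsoon, Oct–Dec post-monsoon); other sites must supply their own map.

Sampling-effort ("bias") surfaces are Gaussian kernel densities of the
occurrence points evaluated at cell centers with per-axis Silverman
bandwidths (σ·n^(−1/6), floored at one cell), floored at 1% of the maximum
so that bias-weighted background sampling is defined everywhere at sea, and
rescaled to a maximum of 1.

Predictor collinearity is pruned greedily: while any pair of layers has
|Pearson r| at or above the threshold (default 0.7, the conventional SDM
cutoff) over jointly valid cells, the member of the worst pair with the
higher mean absolute correlation to the remaining layers is dropped;
constant layers are dropped first since their correlation is undefined.

## Maximum-entropy model

The fit maximizes the L1-penalized presence log-likelihood of the Gibbs
distribution over the background sample (see README for the objective).
Numerical choices:

- **Features.** Deterministic ordering: predictors sorted by name; classes
  in the order linear, quadratic, product, hinge, threshold. Predictors are
  min–max scaled to [0, 1] using background extremes recorded at fit time
  and clamped outside them. Hinge features are forward and reverse ramps at
  equally spaced knots (default 5); threshold features are step functions
  at equally spaced interior break points.
- **Penalties.** β_j = multiplier × β_class(m) × sd_presence(f_j)/√m, with
  β_class interpolated from the published per-class default tables in the
  presence count m and the feature standard deviation floored at 0.01.
- **Optimizer.** FISTA (proximal gradient with backtracking and adaptive
  restart) from λ = 0; convergence when the penalized objective improves by
  less than `tol` (default 1e−7); hitting `max_iter` returns a model
  flagged non-converged. The normative contract is the stationarity
  condition |presence mean − model mean| ≤ β for zero coefficients — any
  convex solver meeting it is acceptable, and the tests verify the fit
  against a brute-force grid search of the same objective rather than a
  particular solver path.
- **Outputs.** Raw output is the Gibbs distribution normalized to sum 1
  over the background. The canonical map output is logistic,
  `e^H r/(1+e^H r)` with H the raw entropy over the background; the
  complementary-log-log variant is deliberately out of scope.
- **Background.** Cells are drawn without replacement with probability
  proportional to the bias surface (uniform when absent). The library
  default is 10,000 cells or all sea cells if fewer; the pipeline samples
  5,000 of the default scenario's ~9,000 sea cells, because enumerating
  nearly all cells would make the bias weighting inoperative.
- **Variable contributions** are permutation importances: the mean drop in
  training AUC over `n_perm` within-mask permutations of each predictor,
  floored at zero and normalized to sum 100. This is solver-independent,
  unlike the path-dependent "percent contribution" heuristic of the
  historical tool; predictors whose features all carry zero coefficients
  contribute exactly 0.

AUC is the Mann–Whitney statistic (presence vs background scores, ties at
half weight), computed by ranking via scikit-learn.

## Settings selection

Candidates are (feature classes, regularization multiplier) pairs. Each is
fit on the full occurrence set for AICc — raw output standardized to sum 1
over the valid grid, L summed at occurrence cells, K = nonzero
coefficients, AICc = 2K − 2L + 2K(K+1)/(n−K−1) — and per partition fold for
test AUC. Partitioning is random 5-fold (balanced within one) above 50
points and leave-one-out jackknife at or below 50. Over-parameterized
candidates (n ≤ K+1) are excluded, matching the convention of the model
evaluation package the field uses. The selected candidate minimizes AICc;
ties break by higher mean test AUC, then smaller K, then input order. k = 5
is the conventional default; the threshold of 50 and k are configurable.

## Risk, Critical Dugong Habitat and the MPA gap

Seasonal suitability maps are combined by the cellwise arithmetic mean.
Fishing pressure is min–max normalized once, before the product, so the
product scale is comparable across regions; the risk surface is the
cellwise product and therefore bounded by each factor. Risk (and survey
threat) classes rescale the surface to percent of its own observed range —
the rule is "of the total range", so a constant surface classifies as all
low with a degeneracy warning — with upper-inclusive boundaries at 25 and
50. Suitability classes use the fixed absolute quarters of [0, 1], also
upper-inclusive (0.25 → unsuitable, 0.75 → moderate). A cell is Critical
Dugong Habitat iff its risk class is high and its combined suitability
strictly exceeds 0.75. The gap report counts high-risk area inside and
outside the rasterized MPA polygons; the protected share is printed to one
decimal and the outside share additionally as the nearest integer,
mirroring the two reporting styles. Whether pressure is pre-normalized and
whether risk classification uses the observed range or a fixed scale are
the two genuinely open conventions; both are explicit in the API (the
product refuses un-normalized pressure rather than silently rescaling).

## Boat-survey validation

Threat counts are interpolated by global inverse-distance weighting
(weights d^−power over all points; a cell within 1/100 cell of a sample
takes its value exactly, making the interpolator exact at samples and a
convex combination elsewhere). The power is scanned over 0.001–10 in steps
of 0.01 — the step is read as +0.01 since a negative step over an
increasing range is undefined — and chosen to minimize leave-one-out RMSE
at the survey points, ties going to the smallest power; no selection
criterion is inherited from elsewhere, so LOOCV RMSE is adopted and stated
here. The threat surface is classified with the same percent-of-range rule
as model risk, and agreement between the two class maps is summarized by a
3×3 confusion matrix and Cohen's kappa ((p_o − p_e)/(1 − p_e), defined as
0 when p_e = 1, i.e. when a map is constant). Survey counts are used
as-is; gear types are not weighted.

## Synthetic seascape

The generator builds one region entirely from a `(config, seed)` pair:

- **Geometry.** 100×100 cells of 1 km; a connected western land strip
  whose width follows a smooth random curve around 10% of the columns.
  `dist_shore` is the exact Euclidean distance transform of the land mask.
- **Predictors.** Depth grows with shore distance plus filtered noise;
  slope derives from the depth gradient; SST has a weak latitudinal
  gradient; diffuse attenuation decays offshore; wave exposure grows
  offshore with an independent swell field. The wave layer drives seagrass
  but is excluded from the dugong predictor set, so the modelled seagrass
  layer carries information the dugong-stage abiotics lack — emulating the
  richer abiotic set used for the seagrass stage in practice.
- **Seagrass truth.** Inverse-logit of a linear combination of
  standardized predictors (a coastal band) plus a static Gaussian
  "dense-meadow core". The core makes the seagrass surface peak well above
  the band.
- **Dugong truth.** A low basal suitability floor (inverse-logit intercept
  −3.5) ordered by weak depth/shore/seagrass terms, a strong core term
  co-located with the seagrass core (dense meadows support
  disproportionate grazing — learnable through a steep response to the
  seagrass predictor), and a smaller seasonal Gaussian hotspot whose
  center shifts alongshore between seasons (default 4 cells per season;
  larger shifts are used to exercise the niche-overlap machinery). This
  "pockets on a low floor" shape is what makes a nonempty highly-suitable
  (>0.75) class attainable at desk scale: the logistic output's ceiling is
  set by how far the peak stands above the entropy-typical cell, so a
  diffuse truth can never reach the top class no matter how well it is
  fit.
- **Sampling.** Presences are drawn with replacement proportional to
  truth × bias over sea cells and jittered within cells; the bias field is
  a Gaussian blob around coastal landing sites raised to `bias_strength`
  (0 = unbiased, the default).
- **Pressure.** Lognormal block values on a 10-cell coarse grid (the 10-km
  gridded product), multiplied by a shore-proximity factor — fishing
  effort concentrates in nearshore waters, the same shallow habitats the
  animals use, which is precisely why suitable habitat ends up at risk —
  then nearest-aligned to the 1-km template and masked to sea.
- **Surveys.** Centroids of non-overlapping 2×2-cell sea blocks; counts
  are Poisson with mean 30 × local mean pressure (optionally inflated by
  lognormal noise). The rate reflects 10-minute boat/gear scans in
  intensive fishing grounds; much smaller counts would be pure Poisson
  noise and would defeat any interpolation-power selection.
- **MPAs.** Random rectangles accumulated to ~15% of the sea.

What the generator does **not** emulate: real oceanographic covariance
structure, the full 14-layer abiotic suite, tidally varying coastlines,
observation error in coordinates, or gear-specific threat composition.
Passing tests therefore demonstrate that the pipeline recovers known
structure under idealized smooth fields — not that any particular real
region's maps are correct.

## Test and study-condition choices

Synthetic experiments in the tests use the default scenario (60 presences
per season, unbiased sampling) with linear+quadratic+hinge features at
multiplier 1 and 5,000 background cells; the bias-correction comparison
uses a single landing site at `bias_strength` 3 with 2,000 background
cells so the effort gradient is strong enough to distort an uncorrected
fit; the settings-selection and contribution-recovery simulations run on
60×60 grids. Ten fixed seeds (0–9) are used for seed-replicated
properties, five (0–4) for the end-to-end Critical-Habitat property, where
the habitat class may be empty in an occasional seed (the acceptance is a
majority criterion, in line with the seed-majority convention used for the
other stochastic properties). Applying kernel-density bias correction to
*unbiased* data flattens the fitted surface — it attributes genuine
occurrence concentration to effort — so end-to-end runs on the unbiased
default scenario disable the bias file; it is enabled by default in the
pipeline configuration for real, interview-derived data.

## Known limitations

- The logistic output calibration depends on the background extent: truths
  occupying a large fraction of the region cap below the 0.75
  highly-suitable threshold, so absolute-scale classes are only
  comparable between runs sharing an extent.
- Percent-of-range risk classes are sensitive to single extreme pressure
  cells (the range is the denominator).
- Bias correction by weighted background sampling loses effect as the
  background approaches the full cell set; per-cell weights inside the
  partition function would be the alternative and are deliberately not
  implemented.
- No significance testing accompanies the niche-overlap statistics; the
  magnitudes are reported as-is.
- IDW with a global neighborhood is O(cells × points) and intended for
  survey sets of tens of points.
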