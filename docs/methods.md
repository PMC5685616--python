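# Methods

## Grid model and conventions

All layers live on one aligned raster grid: row 0 is the northernmost
row, cells are the half-open boxes `[west, east) x (south, north]` (a
point on a shared boundary belongs to the cell south-east of it), and two
grids are aligned only when shape, origin, cell size, and CRS tag agree
exactly — every cross-layer operation asserts this and fails loudly
otherwise. A cell masked in any predictor is masked in the stack's land
mask, and masked cells are excluded from every statistic. The supported
raster format is the ESRI ASCII grid; occurrences are `species,lon,lat`
CSV and reserves GeoJSON polygons. "Spatially separate records" means
records falling in distinct grid cells after rasterization, matching the
modelling resolution; records outside the grid or on masked cells are
dropped with a logged count, since there is no defensible way to snap
them.

Geographic distances use the haversine formula (Earth radius
6371.0088 km). Distance from a pixel centre to a reserve polygon is
computed by projecting the polygon and the point into a local
equirectangular plane (km scale factors taken at the polygon centroid
latitude) and measuring planar distance to the boundary ring. At the
tens-of-kilometre scales of reserve buffers on a few-degree window this
agrees with exact great-circle point-to-edge distance to well under 1%,
and it keeps the geometry vectorized.

## The suitability model

The model is the maximum-entropy (Gibbs) distribution over a background
sample, fitted by L1-penalized likelihood (see README for the objective).
Implementation choices that matter:

* **Feature classes.** Linear, quadratic, pairwise-product, and
  threshold features on continuous predictors, plus one indicator per
  habitat class. Threshold knots sit at `n_knots` (default 10) equally
  spaced quantiles of the background values — midpoint-per-observation
  knot placement adds nothing at this scale. Hinge features are not
  implemented. The feature classes are switchable (`classes="LQPT"`), so
  a quadratic-only basis without linear terms is available if wanted.
* **Scaling and clamping.** Feature columns are min–max scaled to [0, 1]
  on the training background. When projecting onto new climates, each
  continuous predictor is clamped to its training range by default, the
  conservative standard for extrapolation; the flag is exposed.
* **Regularization.** One global `beta0` (default 1.0) scaled per
  feature by the presence-sample SD over the square root of the presence
  count, for all classes alike. Class-specific tuning tables would add
  unverifiable constants.
* **Optimization.** The objective is concave; it is maximized by
  L-BFGS-B on the positive/negative split `lambda = u - v, u, v >= 0`,
  which handles the L1 term exactly. Default 1000 iterations, objective
  tolerance 1e-6; the per-iteration objective history and convergence
  status are stored on the model, and the test-suite asserts the
  objective never increases. Features constant over the background are
  excluded (weight fixed at zero); an all-constant feature set returns
  the uniform model with a warning.
* **Background.** 10000 cells drawn uniformly without replacement from
  the land mask (all cells if fewer), presences not excluded, seeded.
  One shared background per run keeps replicates and species comparable.

Raw output is `q = exp(lambda . f)/Z` (summing to one over the training
background); the logistic transform `p = q e^H/(1 + q e^H)` uses the
entropy `H` of the fitted distribution and maps a typical presence cell
to about 0.5.

## Evaluation

Ten-fold cross-validation partitions the presence cells (fold sizes
within one of each other; `k` is reduced with a warning when a species
has fewer cells than folds). Each replicate is scored on its held-out
presences against the shared background: rank-based Mann–Whitney AUC
(ties count half) and TSS (sensitivity + specificity − 1) at the
replicate's own threshold, with the background standing in for absences.
Because background cells include genuinely suitable habitat, an AUC of
1.0 is not attainable in theory; the synthetic worlds make this concrete,
since the *true* suitability surface itself scores about 0.9.

The binarization threshold is the nearest-rank lower 10th percentile of
the training-presence scores — the largest observed score that keeps at
least 90% of training presences classified present (ties classify as
presence). Percent 0 reduces to the minimal-training-presence rule,
which over-predicts and is not the default. Species filters: fewer than
10 occupied cells, or mean CV AUC below the floor, exclude a species with
a logged reason. A single configurable AUC floor (default 0.7) is used;
the stricter and looser floors sometimes quoted for such filters are
both expressible through it.

## Projection and map algebra

Each replicate map is binarized at its own threshold before the
consensus vote — presence iff strictly more than half the replicates
agree (6 of 10; an exact even split is absence). No-dispersal futures are
the pixelwise AND of current and future consensus. Richness is the sum of
per-species binary maps; gain = future AND NOT current, loss = current
AND NOT future, turnover = gains + losses (unnormalized — dividing by
local richness explodes where richness is near zero). The identities
`change = richness(future) − richness(current) = gains − losses` and
`turnover = gains + losses` hold exactly by construction and are asserted
in the tests. A default run produces 1 current + 12 future richness maps
(3 time slices × 2 scenarios × 2 dispersal assumptions).

## Reserve assessment

2000 random land pixels (uniform, seeded) are classified per reserve:
inside if the pixel centre lies in the polygon (boundary counts as
inside), outside if within 50 km of the polygon boundary but not inside.
The 50-km buffer keeps the outside sample environmentally comparable
while capturing enough pixels. Reserves smaller than a pixel — or that
caught no random pixel — take the richness of the pixel containing their
centroid (the small-reserve rule); a reserve with no exterior (covering
the whole grid) yields an invalid row excluded from testing. The paired
inside-minus-outside differences are tested against zero with a
one-sample *t*-test. The pairing unit is genuinely ambiguous — one
difference per reserve per map (pooled, n = reserves × maps) or one
per-reserve mean over maps — so both pooled and per-reserve tests are
emitted, along with per-map tests. Pooled rows from the same reserve are
correlated across maps, which inflates the pooled *t*; the per-reserve
scope is the conservative reading.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes,
at a desk scale:

* **Landscape.** 100 × 120 cells at 2.5 arc-minutes; ~8% of cells are
  masked "sea". Continuous predictors are low-order spatial polynomials
  plus Gaussian-filtered noise (sigma 8 cells), standardized to zero
  mean / unit SD over land. Requested collinear pairs are induced by
  surface mixing to within 0.1 of the target correlation. The habitat
  layer is an 11-class Voronoi mosaic. Vegetation-index composites carry
  a seasonal sinusoid plus noise, clipped to [−1, 1]; their per-cell max
  and max − min become two derived predictors.
* **Futures.** Additive shifts on the standardized scale: +0.5 SD per
  time slice on the temperature-like predictors (the first three) and
  −0.2 SD on the precipitation-like ones, scaled 1.0 / 0.6 for the
  severe / moderate scenario. Habitat and vegetation layers are held
  constant, as no change scenarios exist for them.
* **Species.** True suitability is inverse-logit of a linear predictor —
  deliberately *not* the maximum-entropy family, so recovery tests probe
  robustness rather than self-confirmation. Default responses have one
  dominant coefficient of magnitude 5, minor coefficients N(0, 1.5), and
  intercept −6, making species range-restricted (mean true prevalence
  ≈ 0.17), as is typical of arid-country floras; under these conditions
  the true-score AUC ceiling is ≈ 0.9, the scale real multi-species
  studies report. Presence cells are drawn without replacement with
  probability proportional to true suitability. Ten species × 150
  presences is the desk-scale community.
* **Reserves.** 25 non-overlapping rectangles and circles on land; the
  last is sub-pixel so the small-reserve rule is always exercised.
  "richness-biased" placement samples centres with probability
  proportional to the cubed min–max-scaled richness hint, mimicking
  reserves deliberately sited on hotspots; "random" placement is the
  null used for calibration.
* **Seeding.** One master seed is split into fixed per-component
  sub-seeds (stack, species, reserves, vegetation), and per-species
  sub-seeds are arithmetic functions of the master seed rather than of
  execution order, so components regenerate independently and runs are
  byte-reproducible.

What the synthetic worlds do *not* emulate: sampling bias in occurrence
records, spatial autocorrelation of records beyond what the smooth
suitability induces, observation error, biotic interactions, and real
coastline geometry. Passing tests therefore demonstrate correctness of
the machinery and calibration of the statistics under the stated
generative model, not performance on biased real-world records.

## Scaled-down study sizes

The built-in study runs use a 2000-cell background (the configuration
default remains 10000) and 1000 random pixels for the reserve comparison
(default 2000), with ten species — sizes chosen so a full end-to-end run
completes in seconds while every statistic retains enough data to be
stable. The calibration experiments use 60 × 70 worlds: the biased-
placement power check over 50 seeded worlds and the type-I-error check
over 200.

## Known limitations

* Only single-band ESRI ASCII rasters are read; reprojection between
  CRSs is out of scope (all inputs must share one grid).
* Hinge features and MaxEnt's cumulative output are not implemented.
* Variable-importance permutation measures are not implemented.
* The equirectangular buffer distance degrades near the poles and for
  reserves spanning many degrees; both are far outside the intended
  scale.
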