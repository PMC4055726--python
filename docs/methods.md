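# Methods

This note documents the models and procedures implemented in `pondsight`,
their assumptions, the parameter defaults and why they were chosen, the
numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## Coordinate and raster conventions

All geometry is planar Cartesian metres (a projected grid); no geographic
CRS handling, reprojection, or datum transforms. Rasters are square-celled;
in memory row 0 is the *south* edge and cell `(r, c)` has its center at
`(x0 + (c + 0.5)·s, y0 + (r + 0.5)·s)`. On disk the canonical format is the
ESRI ASCII grid (north row first; the reader flips). Writing then reading is
bit-exact: values are formatted as integers when integral, otherwise with
`repr`, which round-trips IEEE doubles. GeoTIFF is not supported; the
`dialect` parameter exists so another format can be added behind the same
interface.

## Cumulative viewshed analysis

**Definition.** An observer stands `eye_height` (default 1.5 m) above the
bilinear-interpolated DSM surface at points spaced `spacing` (default
100 m) of arc length along each road polyline (arc positions `0, spacing,
2·spacing, …` strictly below the total length, so the first vertex is always
included and a short road yields exactly one point). A target cell within
`max_distance` (default 500 m, horizontal 2-D distance to the cell center)
is visible when no surface sample strictly between observer and target rises
strictly above the straight 3-D sight line. Samples are taken every
`los_step` metres (default `cell_size / 2`) along the ray, endpoints
excluded; the surface is bilinear-interpolated at each sample. The target
elevation is the bare surface value of its cell — no target-height offset,
because the target is the water/ground parcel itself; only the observer has
a height offset.

**Tie and edge rules** (all deterministic):

- a sample elevation exactly equal to the sight line does **not** block
  (grazing rays count as visible);
- endpoint exclusion prevents the observer's own ground and the target's own
  surface from self-occluding; the observer's own cell is always visible;
- nodata cells block nothing and are never visible;
- no earth-curvature or refraction corrections (sight lines of ≤ 500 m).

**Implementation.** The production path is a numba-compiled per-observer
kernel with early exit on the first blocking sample; the same definition is
implemented twice more — as the pure-Python `line_of_sight` (the public
per-target form) and as an independently written ray-marching oracle inside
the test suite, which the engine must match cell-for-cell on random
terrains. Bilinear interpolation in the engine blends columns before rows
and the test oracle blends rows before columns; agreement therefore also
guards against blend-order sensitivity (exact ties between a sample and the
sight line have measure zero on continuous terrain).

A pond's **visibility score** sums the count grid over the cells whose
centers fall inside the pond polygon (boundary centers count as inside).

## Landscape metrics

- **Ring buffers.** "Within *d* m of the pond edge" is implemented as the
  outward ring `buffer(poly, d) − poly`, excluding the water surface, since
  including it would dilute the surrounding densities with open water; the
  choice is exposed as the buffer being a ring rather than a disc. Arcs use
  16 segments per quadrant (chord error < d/64).
- **Road density** = clipped road length / ring area (m/m²); **urban
  ratio** = urban area / ring area, from polygons (exact) or a category
  raster (cell-count ratio, always in [0, 1]); **river densities** over the
  graded buffers 5, 10, 25, 50, 100, 250, 500, 1000 m. Internally densities
  are m/m²; CSV export scales road and river densities by 10³ (the
  conventional 10⁻³ m m⁻² display unit), stated in the column names.
- **Connectivity** is a path property on a typed directed graph over
  reservoir / canal / pond / farmland nodes: class 2 when some reservoir
  reaches the pond along a path whose intermediate nodes are canals only;
  class 1 when it is reachable only through intermediate ponds or farmland;
  class 0 when unreachable. Direct dominates when both path types exist.
- **Pond area** comes from the polygon (shoelace), not its rasterization.
- **Trophic classes** from chlorophyll *a*: hypertrophic ≥ 25 µg/L,
  eutrophic 8–25, `sub_eutrophic` below 8 (the label below the eutrophic
  band is a package convention; the band itself follows the OECD
  categorisation).

## Classification trees

Binary CART for presence/absence, written to be reproducible operation for
operation:

- **Growing.** Best-first recursive Gini splitting. Numeric candidates are
  midpoints of consecutive distinct sorted values (`value < threshold` goes
  left; rules are displayed as `variable ≥ threshold → right`). Categorical
  candidates are the nonempty proper subsets excluding the highest observed
  level (each two-way partition once), in ascending bitmask order.
  Connectivity is treated as an unordered categorical by default. Ties in
  gain break to the earlier variable in declared column order, then the
  smaller threshold / earlier subset; a split must improve the Gini
  criterion by more than 10⁻⁹ (count units), which guards float noise around
  structurally tied partitions. Leaf prediction is the majority class, ties
  predicting "absent". Growth controls default to `min_split = 20`,
  `min_leaf = 7`, `max_depth = 30` — the classic recursive-partitioning
  defaults; with n in the tens to low hundreds, `min_split` is what keeps
  the trees shallow.
- **Pruning.** Weakest-link cost-complexity pruning on misclassification
  risk scaled by the root (majority-class) risk, so the root's relative
  training error is exactly 1. Splits with zero risk gain collapse at
  α = 0, so the first recorded subtree is the smallest subtree attaining the
  full tree's training risk — the standard construction. The recorded
  α-sequence strictly increases while leaf counts strictly decrease to the
  root. On a fixed dataset the sequence (sizes, relative errors, and the α
  values themselves) matches R's `rpart` CP table exactly; that cross-check
  is part of the test suite.
- **Cross-validation.** Seeded uniform (non-stratified) 10-fold partition;
  each fold's tree is evaluated at the geometric means of consecutive
  master-path alphas; `xerror` is pooled held-out misclassification over the
  full-data root risk, and `xstd` follows the per-case-loss convention
  `sqrt(mean((L − mean L)²)/n) / root risk` for 0/1 losses L.
- **Selection.** The 1-SE rule picks the smallest size with
  `xerror ≤ min(xerror) + xstd_at_min`. Fifty cross-validations
  (consecutive seeds) vote; the **modal size** wins (ties to the smaller
  size) and the full-data tree is pruned to it. "Modal optimal tree" is
  operationalised as modal *size* — tree identity across repeats is
  underdetermined — and the per-size and per-first-split-variable vote
  counts are reported alongside.
- **Evaluation** is apparent (full-data) error by design, matching how the
  optimal tree is scored against the whole survey; misclassification,
  sensitivity and specificity are kept as exact fractions, with display
  rounding half-up to whole percent / two decimals.

## Synthetic landscapes and planted rules

The generator emulates the *structure* of a pond-dotted agricultural
landscape rather than any particular place: Gaussian-hill terrain; an
urbanised southern strip (land-use mix woodland/farmland/urban =
0.36/0.46/0.18) whose building blocks (5–15 m tall) obstruct sight lines; a
jittered road grid, denser inside the urban strip; meandering rivers;
non-overlapping rectangular ponds with log-uniform areas; a canal graph
wiring ≈ 30% of ponds directly and ≈ 22% indirectly to reservoirs (the
survey's 19 + 14 of 64); chlorophyll *a* log-normal with median 26.2 µg/L
clipped to the printed 1.9–438.8 span; drainage Bernoulli(27/64). All
randomness flows from one seed through named CRC-keyed substreams, so any
component regenerates independently.

Presence labels follow planted rules that mirror the *fitted* tree
structures rather than a mechanistic process, because the question the
experiments answer is "can the pipeline recover a known structure":

- species A (bluegill-like): present iff connectivity ≥ 1 **or**
  visibility ≥ τ_v, with τ_v the 65th percentile of pond visibilities
  (interpolated, so it falls strictly between order statistics; an absolute
  viewshed-point threshold would not transfer across landscape scales);
- species B (bass-like): present iff chl-a ≤ τ_c **and** an independent
  Bernoulli(0.75) introduction event, with τ_c the 25th percentile of
  chl-a. The introduction term keeps prevalence (~25–29%) well below rule
  saturation and below species A's, echoing the survey's asymmetry. A
  ceiling at the hypertrophic boundary with a small introduction probability
  was rejected: a rule whose left branch stays minority-class cannot reduce
  misclassification risk at any split, so cost-complexity pruning would
  always return the root and the rule would be unrecoverable by
  construction.
- each label then flips independently with `noise_rate` (default 0.10).

The **coarse mode** used throughout the tests and the acceptance script is
the package's desk-scale configuration: 3 km × 3 km at 5 m cells, 200
ponds with areas 400–10 000 m², observers every 200 m, ray step equal to the
cell size. Full resolution (1 m cells, 100 m spacing, survey-scale pond
areas) is available behind the same interface.

## What the synthetic experiments show — and don't

Passing the recovery experiments shows the chain *viewshed → metrics →
CART* identifies planted decision structure under realistic noise; it does
not validate the ecological model on real landscapes, where presence is not
generated by a crisp rule, visibility errors are spatially structured
(canopy, DSM artefacts), and chl-a covaries with land use. Observers on the
DSM stand on top of canopy or buildings where roads are overhung — the
survey's procedure shares this property, and it is deliberately not
"corrected".

One quantitative limit is worth stating. Across 25 coarse landscapes the
modal trees recover the planted split *variables* in 100% (species A:
connectivity + visibility) and 92% (species B: chl-a) of runs, and the
indicator ordering visibility ≤ road density ≤ urban ratio holds in 96%
with species B's indicators tying in 100%. But the learned numeric
*threshold* lands inside the exact data gap bracketing the planted value in
only ~45–50% of recovering runs at n = 200 and 10% label noise. That is a
property of the estimator, not a defect: the Gini-optimal cut is an order
statistic, and whenever a flipped label lands adjacent to the planted
boundary (probability ≈ ½ at this noise level and sample size) the
empirical optimum shifts by at least one rank — typically a near-miss of
one data point. At n = 500 and 5% noise the same check passes in ≥ 90% of
runs (`tests/test_cart.py::test_planted_threshold_recovery`). The
corresponding end-to-end assertion is kept at its strict bar and documented
as failing for this statistical reason.

## Numerical and degenerate-input conventions

- Division of risks by a zero root risk cannot occur: a pure response grows
  a root-only tree, whose pruning sequence is the single entry `(0, 1, 0)`.
- Pond placement retries are bounded (200 × count); exhaustion raises with
  advice to reduce the count or area range.
- Unseen categories at prediction raise (no surrogate splits, no
  missing-value handling: tables are complete by construction).
- `line_of_sight` rejects targets beyond `max_distance`; the cumulative
  engine filters by radius instead.
- Problem sizes in the test suite (64×64 oracle grids, 25 landscape seeds,
  n ≤ 30 exhaustive-search datasets) are the package's chosen desk-scale
  study conditions, set once alongside the coarse configuration.
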