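# Methods

This note documents the models and procedures implemented by `floodmmi`,
the parameter choices that matter, and what the synthetic-data tests do and
do not demonstrate about real data.

## Assessment model

The condition of a river-corridor assessment site is scored from a single
categorical land-cover raster in three stages.

**Reclassification.** Raw cover codes are binned to five land-use groups
ordered along a disturbance gradient, each carrying a sub-score weight:
unmanaged cover (open water, ice/snow, forest, shrub, herbaceous and
wetland codes 11, 12, 41, 42, 43, 52, 71, 90, 95) at 1.0; pasture/hay
(81) at 0.8; cultivated crops (82) at 0.5; developed open space and
low-intensity development (21, 22) at 0.2; medium/high development and
barren (23, 24, 31) at 0.0. Water and wetlands count as unmanaged without
special-casing: the model assesses divergence from characteristic
floodplain cover, which includes them. Collapsing unmanaged against
everything else gives the binary map for the fragmentation analysis.

**Structural classification (MSPA).** The binary map is decomposed into
seven mutually exclusive structural classes by mathematical morphology:

1. *Core* — foreground whose Chebyshev distance to the nearest background
   pixel exceeds the edge width.
2. *Islet* — foreground components containing no core.
3. *Edge* — non-core pixels within the edge width of their own component's
   core (inner perforation boundaries are part of this rind).
4. Remaining foreground forms connector components: *bridge* if adjacent
   (directly or through a core patch's rind) to two or more distinct core
   patches, *loop* if attached to a single core patch through two or more
   disjoint contact patches on its rind, *branch* otherwise.
5. Background is *managed*.

Weights: core 1.0, edge 0.8, loop and bridge 0.6, branch 0.4, islet 0.2,
managed 0.0. This is a deliberately simplified member of the MSPA family:
it reproduces the seven-class partition that the fragmentation metric
weights, not the byte codes of the JRC GUIDOS tool (a correspondence table
is included for users comparing outputs; GUIDOS features not consumed by
the metric — core-opening sizes, multi-width passes, transition pixels —
are omitted). Design choices: off-grid pixels are foreground, so analysing
a map clipped to a study area does not manufacture edge along the clip
line; connected components are nevertheless labeled on the actual grid
only, since joining patches through virtual off-grid foreground would be
unphysical. Foreground connectivity defaults to 8 with Chebyshev
(8-neighbour) geometry for the erosion and rind so connectivity and
morphology agree; edge width defaults to 3 pixels, reading the 90-m rind
of a 30-m product as edge width rather than minimum core patch width (both
readings are supported through the `edge_width` flag). Nodata acts as
background for the morphology and passes through unchanged.

**Metrics and index.** Both metrics are area-weighted mean sub-scores
(Σ C·w / N) over an assessment mask; N counts assessed (non-nodata) pixels
only, so masked-out pixels neither reward nor penalise a site. Floodplain
and buffer masks are scored separately and combined as
`((Met_BP + Met_BF)/2 + Met_FP + Met_FF)/3`: the buffer metrics are
averaged first because the buffer conditions the floodplain rather than
being part of it. Scores are carried at full floating precision and
rounded only in reports, where 2 decimals are displayed.

## Error model

**User's probability matrix.** The product's confusion matrix (mapped
class rows × reference class columns) is aggregated to the analysis
classes by summing all cells whose row and column map to each group pair —
an operation that can only move confusion onto the diagonal, hence never
lowers overall accuracy — and each row is normalised to a probability
distribution. Row-wise (user's accuracy) normalisation is chosen over
column-wise (producer's) because the map user's question is "what is this
mapped pixel really?". Percent-formatted matrices are accepted and
renormalised. The packaged default UPMs are: five-class rows with
retentions 93.10 / 77.29 / 88.05 / 65.40 / 72.29 %, and binary rows
93.10 / 89.61 %.

**Confusion frequency simulation.** Per realization, every non-nodata
pixel is independently redrawn from its mapped class's UPM row by placing
one uniform(0, 1) draw on the row's inverse CDF, in the fixed group order,
which makes realizations bit-reproducible across platforms. Per-realization
generators derive from a seed sequence keyed by (master seed, realization
index, map kind), so the perturbation and fragmentation ensembles are
independent streams and the ensemble could be parallelised without
changing results. The structural classification is recomputed on every
simulated binary map.

**Autocorrelation filter.** Misclassification in thematic products
concentrates at patch boundaries (mixed pixels, misregistration) rather
than appearing as salt-and-pepper noise inside patches. A 3×3 window
labels each pixel interior (all 8 neighbours, off-grid treated as
same-class, share its class) or edge, once, on the input map — the filter
expresses a property of the original patch structure, not of a
realization. With total gradient `f` (default 0.10, i.e. a 10 %
interior-edge contrast; 0.20 offered for sensitivity analysis), retention
shifts by +f/2 on interior and −f/2 on edge pixels, clamped to [0, 1], and
the off-diagonal row mass is rescaled proportionally. Shifting the
retention probability is sampling-equivalent to shifting the uniform draw
and yields a cleaner testable contract. The additive (percentage-point)
reading of the shift is the default; a multiplicative mode that scales the
misclassification mass by 1 ∓ f/2 is available since the verbal definition
of such filters admits either reading. Two degenerate cases are defined
explicitly: a row with zero misclassification mass has nothing to
redistribute and is returned unchanged, and a retention pushed past 1 is
clamped with the off-diagonals set to zero. Note the clamp means a
retention of 0.93 reaches 1.0 at f = 0.14: under the 20 % filter,
interior pixels of high-accuracy classes never flip, which is what drives
simulated means back toward naive scores.

**Summaries.** Each site/metric ensemble is summarised by its arithmetic
mean (chosen over the median as the conservative central estimate of an
un-modelled distribution), the empirical 2.5th/97.5th percentiles (linear
interpolation between order statistics; alternatives differ by far less
than reporting precision at n = 1000), and the bias naive − mean, reported
both as a score difference and in percentage points (×100). Between-site
differences use a paired two-sided Wilcoxon signed-rank on
per-realization index scores — paired, because realizations are indexed by
a common stream; identical ensembles are reported as p = 1.0 directly,
since rank statistics are undefined on all-zero differences. No
multiple-testing correction is applied to the pairwise matrix by default,
matching common reporting practice; callers can correct the returned
p-values if desired.

## Synthetic data

The generator stands in for a 30-m classified product clipped to digitised
assessment sites. Landscapes are Gaussian white noise blurred at sigma
`patch_scale` (periodic boundary) with noise quantiles mapped to classes
at the requested proportions — proportion-exact up to rounding and ties,
spatially contiguous, deterministic per seed. Sites pair a rectangle or
sinuous-band floodplain with a buffer formed by Chebyshev dilation
(`buffer_width` pixels, emulating a fixed-width buffer zone; a zero-width
buffer is rejected as degenerate). Confusion matrices are drawn row-wise
from a multinomial with the requested diagonal mass spread evenly over
off-diagonals.

What this emulates: patch-structured categorical maps spanning a
disturbance gradient, with diagonally dominant accuracy data. What it does
not: hydrologically realistic corridor geometry, georeferencing,
anisotropic or class-dependent patch shapes, spatially structured
reference error, and non-thematic error sources (misregistration). Tests
passing on these landscapes demonstrate the correctness and calibration of
the machinery — not that any particular real floodplain's bias matches the
synthetic one.

**Demonstration fixture.** The direction-of-bias analysis uses a 96×96
landscape whose left half is homogeneous unmanaged forest and whose right
half mixes five classes at proportions (0.35, 0.30, 0.15, 0.12, 0.08)
with `patch_scale` 14 — interior fractions around 0.85–0.9, typical of
smoothed Landsat-derived valley maps whose fields and forest blocks span
tens of pixels; one 48×20-pixel site with a 4-pixel buffer sits in each
half, scored over 200 realizations per filter setting. On this fixture the
homogeneous site's index bias is positive (misclassification can only
degrade a perfect landscape) and larger than the mixed site's, and the
20 % filter moves simulated means toward the naive scores. The
toward-naive trend is a property of interior-dominated maps: on heavily
fragmented maps (interior fraction near one half) the edge-side retention
loss can dominate and reverse it.

## Numerical and I/O choices

- Rasters travel as ESRI ASCII grids (self-describing text, nodata in the
  header) or single-band TIFF; no CRS handling — pixel size is metadata
  the analysis never uses.
- Class order is fixed end-to-end by the scheme's `group_order` (file
  order for CSV inputs) and is the sampling order of the inverse CDF.
- The distance transform marks background-free maps as infinitely deep,
  so an all-foreground raster is all core.
- Output CSVs are written with a fixed float format, making full pipeline
  runs byte-identical for identical config and master seed.
- Problem sizes in the test suite and acceptance script (96–128 pixel
  grids, 200 realizations) were chosen to exercise every code path with
  Monte Carlo error well below the effect sizes asserted; the ensemble
  machinery itself is size-agnostic and the 1000-realization default of
  `RealizationRun` reflects standard practice for production runs.

## Known limitations

- The simulation assumes pixel-independent error conditioned on the
  interior/edge split; real spatial error structure (variograms,
  misregistration) is out of scope.
- User's-accuracy rows inherit all uncertainties of the product's own
  accuracy assessment (continental-scale reference sampling, reference
  label error); the model propagates, not audits, them.
- The structural classification is not byte-compatible with GUIDOS MSPA;
  partition-level agreement is what the fragmentation metric requires.
- Vector site geometries are unsupported: sites are raster masks.
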