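# Methods

This note documents the models and procedures implemented in `forestchange`,
the parameters that matter, what the synthetic scene generator does and does
not emulate, and the design choices made where the method left room.

## Overview of the procedure

The pipeline maps forest loss between consecutive years from Sentinel-2-like
10-band surface-reflectance imagery in five stages:

1. **Reference sampling.** Labelled points are drawn from an existing (and
   imperfect) land-cover product under three rules: a 10 m internal buffer
   away from class edges, a minimum spacing of 20 m between points, and a
   density cap of 2 points per km² of class area. Each point carries three
   attributes: land-cover class, forest/non-forest, and coniferous/
   broadleaved (for forest points). Labels are then verified spectrally
   (below) and split 60/40 into training and validation per class.
2. **Two-stage classification.** A random forest (100 trees, √p candidate
   features per split, unlimited depth, fixed seed) first separates forest
   from non-forest on the stacked multi-date band values (April–September
   window); a second random forest labels the dominant leaf type only inside
   the forest mask. Models are trained per scene; a fitted model can be
   transferred unchanged to another scene with the same feature schema, the
   regime used where forest is too sparse to train locally.
3. **Index differencing.** June–August median mosaics are built per year;
   NDVI = (B8−B4)/(B8+B4) and NBR = (B8−B12)/(B8+B12) are computed per
   mosaic and differenced as *year1 − year2*, so vegetation loss is
   positive. Pixels exceeding mean + k·SD (k = 3, statistics over the
   year-1 forest mask) on either difference form the candidate-change mask
   used to guide reference-area selection.
4. **Direct change classification.** A 22-feature stack (10 bands of each
   annual mosaic + dNDVI + dNBR) is classified by a 100-tree random forest
   into {no change, woody→non-woody, burnt forest}. Training points come
   from labelled reference polygons, split 7:3. The model trained on the
   first region and year pair transfers unchanged to other regions and
   periods. Change components of ≤ 400 m² (4 pixels at 10 m) are reverted
   to "no change" (minimum mapping unit).
5. **Accuracy and reporting.** Stratified 10 × 10 m verification polygons
   (100 per class where available, class extents shrunk 10 m inward) are
   compared with the reference to build an error matrix; OA, Kappa, per-class
   UA/PA and F1 are derived from its counts. Change-map pixel counts convert
   to hectares (1 px = 0.01 ha) and aggregate into per-region and pooled
   loss tables with class shares.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| classification window | Apr–Sep | months | vegetation-season acquisitions for cover/leaf classification |
| mosaic window | Jun–Aug | months | peak-season median composite for change detection |
| train fraction (cover/leaf) | 0.6 | – | 60/40 split per class |
| train fraction (change) | 0.7 | – | 7:3 split per class |
| sampling density | 2 | pts/km² | cap per class area; see scaling note below |
| edge buffer | 10 | m | keeps points off mixed boundary pixels |
| minimum point spacing | 20 | m | limits spatial autocorrelation between samples |
| candidate threshold k | 3 | SD | one-sided exceedance on the loss side |
| minimum mapping unit | 400 | m² | components of ≤ 4 pixels are unreliable and removed |
| trees per forest | 100 | – | stated for the change model; used for all tasks for uniformity |
| cloud probability cutoff | 0.65 | – | product convention; configurable |

## Spectral verification of sample labels

The reference product that supplies the labels is itself only ~75% accurate,
so labels are cross-checked against the imagery. Per class and band, the
median and the MAD (scaled by 1.4826 to estimate a standard deviation) are
computed over the candidate points' spectra; a point is discarded when it
falls outside median ± 3 scaled-MADs in more than 3 of the 10 bands. The
rule is robust to up to ~50% contamination in principle, parameter-light,
and testable: on synthetic scenes it provably reduces the mislabelled
fraction. Classes with fewer than 5 points pass through unverified (a
logged warning), since robust statistics on 2–4 points are meaningless.

## The synthetic scene generator

Real acquisitions for this problem are tens of gigabytes and cannot ship
with a package; instead every stage is exercised against generated scenes
with exact truth.

The generator emulates: per-class spectral signatures for eight land-cover
classes (coniferous, broadleaved, sealed, grassland, cropland, bare soil,
wetland, water) plus two post-disturbance surfaces (burnt, cleared), with
per-band Gaussian pixel noise (SD 0.01) and a small seasonal sinusoid over
day-of-year (amplitude 0.005); contiguous class patches via a Voronoi
tessellation of random seed points; 3–5 acquisitions per season; rectangular
cloud masks covering a configurable fraction (default 5%) of each
acquisition; change events (clearings and burns) as polygons applied from
their event year onward; and a mock reference land-cover product made by
relabelling exactly 25% of pixels — matching the ~75% accuracy of global
products — in spatially coherent patches, as misclassified fields and
stands are in reality.

Signature values are plausible growing-season surface reflectances chosen
so that class means sit several noise-SDs apart, the burnt surface has
lower NIR and higher SWIR2 than any woody class (NBR drops after fire), and
the cleared surface has lower NDVI than woody cover. They are stand-ins,
not calibrated to any particular region.

The generator does **not** emulate: radiative transfer, topographic and
BRDF effects, mixed pixels, within-class spatial texture, sensor orbit and
tiling, sub-annual disturbance timing, or spatially correlated noise.
Passing recovery tests therefore demonstrates that the pipeline's logic is
correct and its accuracy reachable under clean class structure — not that
these accuracies would be attained on real imagery, where spectral overlap
between classes is far larger.

## Numerical choices

- Reflectance is float32 in [0, 1] internally; integer rasters declare a
  1/10000 scale factor.
- Even-count medians take the mean of the two middle values.
- Grids are half-open ([row, row+1)); pixel centres sit at half-integer
  coordinates; 20 m → 10 m bilinear resampling aligns pixel centres and
  edge-extends beyond the outermost source centres.
- Index differences are undefined (NaN) where any input band is invalid or
  the denominator is zero; a zero-variance domain yields an empty candidate
  mask.
- The k·SD exceedance is one-sided (loss direction) and the two indices are
  combined by union by default (maximises candidate recall); intersection
  is available in the configuration.
- Minimum-mapping-unit components use 8-connectivity; filtered pixels
  revert to "no change" rather than nodata; the filter is idempotent.
- F1 is the harmonic mean of user's and producer's accuracy. Metrics for a
  class with an empty row or column are reported as undefined (NaN), never 0.
- Percentages round half-up at the printed precision (whole percent for
  class shares, one decimal for cover fractions): a share of 73.51% reports
  as 74%.
- Train/validation assignment takes round(ratio × n) training points per
  class; a single-point class goes to training with a warning.
- Rejection sampling for the spacing rule gives up on a class after 100×
  the target draw count, preventing non-termination under dense constraints.

## Scaling of test scenes

The recovery tests and the acceptance script run on 256 × 256-pixel scenes
(≈ 6.5 km²) — small enough that the whole suite runs in minutes on one CPU,
large enough for hundreds of training points and multiple disturbance
patches. At this extent the published sampling density of 2 pts/km² would
leave rare classes with 0–4 points, which is not the regime the rule was
designed for (regions of ~20 000 km² yield tens of thousands of points,
with per-class counts additionally tuned for sufficiency). The test
configurations therefore raise the density (80 pts/km² for recovery scenes,
150 for the demo regions) so the rarest class still receives a usable
sample; the buffer, spacing and density-cap *rules* are unchanged and are
tested at the published density in the sampling constraint suite.

Classification feature stacks are gap-filled from the seasonal median
composite before stacking, so a cloud mask in a single date does not punch
holes in the classified maps — the counterpart of selecting cloud-free
scenes when working with real archives.

## Known limitations

- The two change classes do not separate clear cuts from forest degradation
  within woody→non-woody conversion.
- Model transfer assumes the target scene shares the training scene's
  spectral regime; transfer across shifted signatures degrades accuracy
  (measured and logged, not bounded).
- Reference areas for change training are taken from configuration (or
  derived from synthetic truth in tests); the manual image-interpretation
  step used with real data is out of scope.
- Only affine pixel grids are handled; no reprojection between coordinate
  reference systems.
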