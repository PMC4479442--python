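# Methods

## Problem and approach

`orchard3d` measures the 3-D geometry of agricultural trees — position,
canopy axes, projected area, height and crown volume — from the two raster
products a UAV photogrammetry workflow delivers: an orthomosaic and a
co-registered digital surface model (DSM). Instead of classifying pixels
independently, the procedure is object-based: the scene is first segmented
into spectrally and structurally homogeneous objects, objects are then
classified (bare soil / herbaceous vegetation / tree canopy), heights are
measured against a locally selected bare-soil baseline, and tree objects
are finally merged into individual trees or tree-rows whose crown volume is
integrated pixel by pixel. This tolerates irregular crown shapes that defeat
solid-geometry formulas such as the ellipsoid model
`V = pi/6 * ((L+W)/2)^2 * H` (provided in `validation.ellipsoid_volume`
as the conventional field reference).

## Segmentation model

Multiresolution segmentation is bottom-up pairwise region merging from
single-pixel seeds. Merging regions 1 and 2 costs

```
f        = w_color * dh_color + w_shape * dh_shape
dh_color = sum_l w_l (n_m s_m - n_1 s_1 - n_2 s_2)        s = population std of layer l
dh_shape = w_cmpct * dh_cmpct + w_smooth * dh_smooth
```

where compactness is `perimeter / sqrt(area)` and smoothness is
`perimeter / bounding-box perimeter`, each deviation weighted by region
size. A merge is accepted while `f < scale^2`.

Defaults: `color_weight 0.6`, `shape_weight 0.4`, `smoothness 0.5`,
`compactness 0.05` (the smoothness/compactness pair is used exactly as
given, as relative weights, without renormalising to sum 1). Layer weights
default to DSM = 1 plus Green = 1 (RGB sensor) or NIR = 1 (multispectral
sensor), all other layers 0 — the layers in which trees are most prominent.
Bands enter the cost on their 8-bit DN scale and the DSM in metres, so the
scale parameter is in weighted-layer DN units; the default `scale = 20`
suits orchard scenes around 2.7 cm GSD. A zero-weight layer provably never
influences the result (it never enters the cost).

Candidate selection is *local mutual best fitting, in rounds*: every region
points at its cheapest neighbour (ties to the smaller region id), all
mutually-pointing pairs below threshold merge simultaneously, and the
region adjacency graph is contracted between rounds. If a round yields no
mutual pair, the single globally cheapest admissible edge merges, which
guarantees progress. The procedure is fully deterministic and runs in
O(edges) per round with incrementally maintained sufficient statistics
(count, per-layer sum and sum of squares, perimeter via shared-boundary
bookkeeping, bounding box), making ~9-megapixel scenes tractable in about
a minute on one core. Region adjacency uses 4-connectivity so crowns do
not leak into each other through diagonals.

## Classification and heights

Vegetation is separated from bare soil by thresholding *per-object mean*
vegetation-index values — ExG = 2g − r − b on chromatic coordinates for RGB
imagery, NDVI = (NIR − R)/(NIR + R) when a NIR band exists. Both indices
are invariant to positive rescaling of the bands, so DN versus reflectance
is immaterial. The threshold is Otsu's method adapted to the object
framework: a 256-bin histogram of object means, each object weighted by its
pixel count, with exact per-bin weighted value sums so that the selected
bin edge is identical to an exhaustive search over all edges. Degenerate
(single-valued) scenes raise an error rather than fabricating a split.

Canopy height is the DSM minus a *local* bare-soil baseline: the median DSM
elevation of bare-soil pixels within a ring of `ring_px = 5` pixels
(chessboard distance) around each vegetation object. The median resists
stray vegetation pixels in the ring; the locality cancels terrain slope
without requiring a terrain model. If the ring holds no soil — the normal
situation for segments in a crown interior, which are surrounded by other
vegetation — the ring doubles repeatedly (up to 64 x `ring_px`, about 5 m
at 1.5 cm GSD) so the baseline comes from the nearest soil around the
crown. Capping the widening too early (e.g. at 4 x) proved to punch holes
into crowns at fine resolutions: interior segments were declared
baseline-failures, relabelled herbaceous, and area/volume errors grew by an
order of magnitude. Objects that still find no soil are conservatively
relabelled herbaceous and logged. Pixel heights are clamped at 0 (a
vegetation pixel below its baseline is measurement noise, not negative
canopy); the object height is the maximum pixel height (the crown apex),
with a 99th-percentile option for noisy DSMs. Vegetation lower than
`min_tree_height = 0.5 m` above its baseline is relabelled herbaceous; the
cut is configurable and fixed rather than re-estimated per scene.

## Tree entities and features

Tree-class objects are merged by 8-connectivity into entities — one per
isolated crown, one per hedgerow where crowns touch along a row — forming
the upper level of a two-level segmentation hierarchy (base objects carry
`parent_id`). Entities below 0.1 m² are dropped as noise, consistent with
the usual four-pixel detectability limit. Per entity:

- projected area = pixel count x GSD²
- height = max pixel height (p99 optional); for rows this is the row
  maximum, with the mean available as an option
- volume = sum over pixels of pixel height x GSD² (volume is therefore
  exactly additive under any split of an entity, and bounded by
  area x height)
- length/width axes = side lengths of the minimum-area oriented bounding
  rectangle of the pixel footprint (moment-ellipse axes available as an
  option); the centroid is reported in map coordinates.

## Synthetic scenes

The generator emulates the study conditions end to end: a plane (default
2 % slope) plus a smooth 0.15 m undulation; half-ellipsoid crowns
(`DSM = terrain + h sqrt(1 - (dx/rx)^2 - (dy/ry)^2)`) on a planting
lattice — presets mirror single-tree blocks at 7x7 m and 8x8 m spacing and
hedgerows at 3.75x1.3 m and 8x4 m, at the four flown resolutions (1.53,
2.71, 3.06, 5.42 cm GSD); herbaceous patches up to 0.3 m tall on 5 % of
the ground; per-class band means with additive Gaussian sensor noise
(default sigma 4 DN, "clean" presets 2 DN); and DSM noise that is spatially
smoothed before rescaling (sigma 0.03 m, clean 0.02 m), mimicking the
correlated error of photogrammetric reconstruction. Crowns give closed-form
truth: area `pi rx ry`, volume `(2/3) pi rx ry h`. Default crown semi-axes
are 1.4–2.2 m and heights 2–4 m, typical of mature olive crowns.

What the generator does **not** emulate: radiative transfer (shadows,
bidirectional effects), photogrammetric failure modes (blurry DSM regions
over low-contrast crowns), within-crown spectral texture, and mixed pixels
beyond rasterisation. Passing tests therefore demonstrate the correctness
and internal consistency of the algorithmic chain under controlled
conditions, not performance on arbitrary field imagery.

## Problem sizes and numerical choices

Unit tests run on small blocks (3x3 trees at 5 cm GSD, ~0.2 Mpx);
acceptance checks run 6x6-tree scenes at 2.71 and 1.53 cm (2.4–3.3 Mpx)
and the headline script five 100-tree scenes at 2.71 cm plus three
36-tree scenes at 1.53 cm (7.5–8.7 Mpx each) — sizes chosen so the whole
chain, including segmentation from single-pixel seeds, stays comfortable on
a single core. Fusion costs are evaluated in float64 and stored as float32;
all candidate selection is vectorised and deterministic, so a fixed
generator seed yields byte-identical GeoTIFFs and identical tree tables
across runs. Rasters must agree within half a pixel; nothing is resampled
implicitly. Zero-denominator index pixels become nodata rather than 0.
GSD is kept in metres internally and rounded half-up to 2 decimals of a
centimetre only for display.

## Known limitations

- The segmentation reproduces the published parameterisation of
  multiresolution merging, not the exact object boundaries of any
  commercial implementation.
- Tree-row plantations report row-level metrics; individual trees inside a
  touching row are not split.
- No radiometric calibration or shadow handling; heavily shadowed crowns
  will thin the detected canopy.
- Very low soil/canopy spectral contrast degrades the Otsu split — by
  design the failure surfaces as a degenerate-distribution error on
  single-class scenes rather than a silent wrong threshold.
- Vector export is GeoJSON (plus CSV tables); ESRI Shapefile is not
  written.
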