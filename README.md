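# orchard3d

Object-based delineation and 3-D measurement of orchard trees from UAV
imagery. Given an orthomosaic and a co-registered digital surface model
(DSM), `orchard3d` automatically finds every tree or tree-row and computes
its position, canopy length/width axes, projected area, height and crown
volume — the quantities growers and agronomists otherwise collect by hand
with rulers and solid-geometry formulas.

The workflow is classic OBIA (object-based image analysis):

1. **Segmentation** — multiresolution pairwise region merging (Baatz–Schäpe
   fusion cost, `f = w_color·Δh_color + w_shape·Δh_shape`, accepted while
   `f < scale²`) on the layers where trees are prominent: the DSM plus
   Green (RGB camera) or NIR (multispectral camera).
2. **Classification** — vegetation vs bare soil by Otsu-thresholding
   per-object means of ExG = 2g−r−b or NDVI = (NIR−R)/(NIR+R); canopy
   height from the DSM against the median elevation of bare soil
   immediately surrounding each object (cancels terrain slope); low
   vegetation (< 0.5 m) relabelled herbaceous.
3. **Tree features** — tree objects merged into entities (trees or
   hedgerow rows), crown volume integrated per pixel
   (`V = Σ height·GSD²`), axes from the minimum-area oriented bounding
   rectangle.
4. **Export** — GeoJSON footprints with full attributes plus a CSV table
   (`tree_id, x, y, length_axis, width_axis, projected_area, height,
   volume`), and per-field summaries.

A synthetic-orchard generator (`orchard3d.synthetic`) produces
georeferenced scenes — half-ellipsoid crowns on sloping, undulating
terrain with grass patches and sensor noise — together with closed-form
ground truth, so the whole chain is testable without any imagery download.
See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
from orchard3d.synthetic import preset_config, generate_orchard, rasterize_truth
from orchard3d.pipeline import run_pipeline, export_result
from orchard3d.validation import overall_accuracy

cfg = preset_config("single_tree_7x7", gsd=0.05, seed=7, n_rows=3, n_cols=3)
scene, truth = generate_orchard(cfg)          # 420x420 px, 9 trees
result = run_pipeline(scene)

print(len(result.records), "trees found")
r = result.records[1]
print(f"tree {r.tree_id}: area {r.projected_area:.2f} m2, "
      f"height {r.height:.2f} m, volume {r.volume:.2f} m3")
mask, ref = rasterize_truth(truth)
print(f"overall accuracy {overall_accuracy(result.tree_mask, mask):.2f} %")
export_result(result, "trees.geojson", "trees.csv")
```

prints

```
9 trees found
tree 2: area 10.44 m2, height 4.00 m, volume 27.75 m3
overall accuracy 100.00 %
```

For that tree the generator's truth is height 3.99 m and volume
27.78 m³ (= ⅔π·rx·ry·h), i.e. the pixel-integrated estimate lands within
roughly 0.1 % of the analytic crown volume at 5 cm GSD.

The same workflow is scriptable from the shell:

```bash
orchard3d synth --preset single_tree_7x7 --seed 7 --out-dir scene/
orchard3d run --ortho scene/ortho.tif --dsm scene/dsm.tif --out-dir out/
orchard3d validate --pred-mask scene/truth_mask.tif --truth-mask scene/truth_mask.tif
orchard3d gsd --pixel-size-mm 0.0052 --focal-mm 9.6 --altitude-m 50
# GSD = 2.71 cm (0.027083 m/pixel)
```

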