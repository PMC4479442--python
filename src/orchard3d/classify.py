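"""Object-level classification: bare soil / herbaceous vegetation / tree.

Vegetation is isolated from bare soil by thresholding per-object mean
vegetation-index values with Otsu's method adapted to the object framework
(each object weighted by its pixel count). Canopy height is then measured
against a *local* bare-soil baseline — the median DSM elevation of bare-soil
pixels in a narrow ring around each vegetation object — which removes
terrain slope without needing a terrain model. Finally, vegetation too low
above its baseline is relabelled herbaceous.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateDistributionError
from .segmentation import SegmentLevel
from .spectral import IndexLayer

log = logging.getLogger(__name__)

BARE_SOIL = "bare_soil"
HERBACEOUS = "herbaceous"
TREE = "tree"

#: histogram resolution of the object-level Otsu threshold
_OTSU_BINS = 256


@dataclass
class ClassMap:
    """Per-object classes and heights above the local bare-soil baseline."""

    object_class: pd.Series                  # object id -> class string
    object_height: pd.Series                 # object id -> m (NaN until computed)
    baseline_elev: pd.Series                 # object id -> baseline DSM m
    pixel_height: np.ndarray | None = None   # m above baseline on vegetation pixels
    baseline_failed: set[int] = field(default_factory=set)
    threshold: float = float("nan")          # the Otsu index threshold used

    def ids_of(self, cls: str) -> np.ndarray:
        return self.object_class.index[self.object_class == cls].to_numpy()


def otsu_threshold(values, weights=None) -> float:
    """Otsu threshold of object mean values, objects weighted by pixel count.

    A 256-bin histogram over the value range is built with the given
    weights; the returned threshold is the upper edge of the last bin of
    the lower class, i.e. the split maximising the weighted between-class
    variance. Values >= the threshold fall in the upper class.
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.ones_like(values) if weights is None else np.asarray(weights, dtype=np.float64)
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateDistributionError(
            "Otsu thresholding needs at least two distinct values"
        )
    rng = (values.min(), values.max())
    hist, edges = np.histogram(values, bins=_OTSU_BINS, range=rng, weights=weights)
    moment, _ = np.histogram(values, bins=_OTSU_BINS, range=rng,
                             weights=weights * values)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    moments = np.cumsum(moment)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = moments / w0
        mu1 = (moments[-1] - moments) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between[:-1], nan=-1.0)
    k = int(np.argmax(between))
    return float(edges[k + 1])


def classify_vegetation(level: SegmentLevel, index: IndexLayer) -> ClassMap:
    """Split objects into vegetation (provisionally tree) vs bare soil.

    The threshold is applied to per-object *mean* index values, so each
    object is classified as a unit regardless of within-object variation.
    """
    means = level.object_mean(index.values, index.nodata_mask)
    counts = level.objects["pixel_count"]
    thr = otsu_threshold(means.to_numpy(), counts.to_numpy())
    cls = pd.Series(np.where(means.to_numpy() >= thr, TREE, BARE_SOIL), index=means.index)
    nan_h = pd.Series(np.nan, index=means.index)
    return ClassMap(
        object_class=cls,
        object_height=nan_h.copy(),
        baseline_elev=nan_h.copy(),
        threshold=thr,
    )


def object_height(
    level: SegmentLevel,
    dsm: np.ndarray,
    classes: ClassMap,
    ring_px: int = 5,
    height_stat: str = "max",
    max_ring_factor: int = 64,
) -> ClassMap:
    """Heights of vegetation objects above their local bare-soil baseline.

    For each vegetation object the baseline is the median DSM value over
    bare-soil pixels within ``ring_px`` pixels (chessboard distance) of
    the object. If the ring holds no bare soil — typical for segments in
    the crown interior, which are surrounded by other vegetation — the
    ring keeps doubling until soil is found or ``max_ring_factor *
    ring_px`` is reached, so the baseline always comes from the nearest
    soil around the crown. Pixel heights are DSM - baseline clamped at 0
    on the object's pixels; the object height is their maximum (the crown
    apex) or, with ``height_stat='p99'``, the 99th percentile for noisy
    DSMs. Objects with no reachable bare soil get a recorded baseline
    failure and an undefined height.
    """
    labels = level.labels
    veg_classes = {TREE, HERBACEOUS}
    veg_ids = classes.object_class.index[classes.object_class.isin(veg_classes)].to_numpy()
    max_label = int(labels.max())
    is_veg_lut = np.zeros(max_label + 1, dtype=bool)
    is_veg_lut[veg_ids] = True
    veg_mask = is_veg_lut[labels]
    soil_lut = np.zeros(max_label + 1, dtype=bool)
    soil_lut[classes.ids_of(BARE_SOIL)] = True
    soil_mask = soil_lut[labels]

    pixel_height = np.full(labels.shape, np.nan, dtype=np.float32)
    obj = level.objects
    for oid in veg_ids:
        row = obj.loc[oid]
        baseline = None
        ring = ring_px
        while True:
            r0 = max(int(row["row_min"]) - ring, 0)
            r1 = min(int(row["row_max"]) + ring + 1, labels.shape[0])
            c0 = max(int(row["col_min"]) - ring, 0)
            c1 = min(int(row["col_max"]) + ring + 1, labels.shape[1])
            win = np.s_[r0:r1, c0:c1]
            obj_mask = labels[win] == oid
            dist = ndimage.distance_transform_cdt(~obj_mask, metric="chessboard")
            ring_mask = (dist > 0) & (dist <= ring) & soil_mask[win] & ~veg_mask[win]
            if ring_mask.any():
                baseline = float(np.median(dsm[win][ring_mask]))
                break
            if ring >= max_ring_factor * ring_px:
                break
            ring *= 2
        if baseline is None:
            classes.baseline_failed.add(int(oid))
            log.warning("object %d: no bare soil within %d px; height undefined",
                        oid, ring)
            continue
        heights = np.clip(dsm[win][obj_mask] - baseline, 0.0, None)
        pixel_height[win][obj_mask] = heights
        classes.baseline_elev.loc[oid] = baseline
        if height_stat == "p99":
            classes.object_height.loc[oid] = float(np.percentile(heights, 99))
        else:
            classes.object_height.loc[oid] = float(heights.max())
    classes.pixel_height = pixel_height
    return classes


def remove_herbaceous(classes: ClassMap, min_tree_height: float = 0.5) -> ClassMap:
    """Relabel low vegetation as herbaceous.

    Vegetation objects lower than ``min_tree_height`` metres above their
    baseline — and, conservatively, objects whose baseline could not be
    found — become herbaceous; the rest remain trees.
    """
    for oid in classes.ids_of(TREE):
        oid = int(oid)
        if oid in classes.baseline_failed:
            classes.object_class.loc[oid] = HERBACEOUS
            log.info("object %d: baseline failure, relabelled herbaceous", oid)
        elif classes.object_height.loc[oid] < min_tree_height:
            classes.object_class.loc[oid] = HERBACEOUS
    return classes


def class_raster(level: SegmentLevel, classes: ClassMap) -> np.ndarray:
    """uint8 class codes per pixel: 0 nodata, 1 bare soil, 2 herbaceous, 3 tree."""
    codes = {BARE_SOIL: 1, HERBACEOUS: 2, TREE: 3}
    lut = np.zeros(int(level.labels.max()) + 1, dtype=np.uint8)
    for oid, cls in classes.object_class.items():
        lut[int(oid)] = codes[cls]
    return lut[level.labels]
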