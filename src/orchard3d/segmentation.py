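"""Multiresolution segmentation by pairwise region merging.

Bottom-up Baatz–Schäpe-style merging from single-pixel seeds. The fusion
cost of merging regions 1 and 2 is

    f = w_color * dh_color + w_shape * dh_shape
    dh_color = sum_l w_l * (n_m s_m - n_1 s_1 - n_2 s_2)          (s = layer std)
    dh_shape = w_cmpct * dh_cmpct + w_smooth * dh_smooth
    dh_cmpct  from compactness  = perimeter / sqrt(area)
    dh_smooth from smoothness   = perimeter / bounding-box perimeter

with each deviation weighted by region size (n * value). A merge is accepted
while f < scale**2. Candidates are selected by local mutual best fitting:
in each round every region points at its cheapest neighbour (ties broken by
the smaller region id) and all mutually-pointing pairs under the threshold
merge simultaneously; if a round produces no mutual pair, the single
globally cheapest admissible edge merges. The procedure is deterministic.

Region adjacency uses 4-connectivity, which prevents diagonal leakage
between neighbouring crowns. Standard deviations use population (1/n)
normalisation, matching the additive n*sigma heterogeneity form.

Spectral bands enter the cost on their 8-bit DN scale (0-255); the DSM in
metres. The scale parameter is therefore in weighted-layer DN units.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .scene_io import SceneStack

#: DN scale applied to [0,1] float bands before computing heterogeneity
_BAND_DN_SCALE = 255.0


@dataclass
class SegmentationParams:
    """Homogeneity parameters of the region-merging segmentation.

    scale : merge-acceptance threshold is scale**2, in weighted-layer DN
        units. Default 20 suits ~2.7 cm GSD orchard scenes; finer rasters
        or stronger contrast may need other values.
    color_weight / shape_weight : must sum to 1.
    smoothness_weight / compactness_weight : relative weights inside the
        shape term, used exactly as given (not renormalised).
    layer_weights : map layer name -> weight; None selects the default
        (DSM plus Green or NIR depending on the sensor, see
        :func:`default_layer_weights`).
    """

    scale: float = 20.0
    color_weight: float = 0.6
    shape_weight: float = 0.4
    smoothness_weight: float = 0.5
    compactness_weight: float = 0.05
    layer_weights: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")
        if abs(self.color_weight + self.shape_weight - 1.0) > 1e-9:
            raise ParameterError("color_weight + shape_weight must equal 1")
        for name in ("color_weight", "shape_weight", "smoothness_weight", "compactness_weight"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.layer_weights is not None:
            if any(w < 0 for w in self.layer_weights.values()):
                raise ParameterError("layer weights must be >= 0")
            if not any(w > 0 for w in self.layer_weights.values()):
                raise ParameterError("at least one layer weight must be > 0")


@dataclass
class SegmentLevel:
    """A labelled partition of the valid pixels plus its object table.

    labels : int32 raster, object id per pixel, 0 = nodata.
    objects : DataFrame indexed by object id with pixel_count, per-layer
        mean_<layer> / std_<layer>, perimeter_px, bbox rows/cols, a
        ``neighbors`` frozenset column and a nullable parent_id.
    """

    labels: np.ndarray
    objects: pd.DataFrame
    layers: dict[str, np.ndarray] = dc_field(default_factory=dict, repr=False)

    @property
    def ids(self) -> np.ndarray:
        return self.objects.index.to_numpy()

    def object_mean(self, raster: np.ndarray, nodata_mask: np.ndarray | None = None) -> pd.Series:
        """Per-object mean of an arbitrary co-registered raster."""
        valid = self.labels > 0
        if nodata_mask is not None:
            valid &= ~nodata_mask
        lab = self.labels[valid]
        vals = raster[valid].astype(np.float64)
        k = int(self.labels.max()) + 1
        counts = np.bincount(lab, minlength=k)
        sums = np.bincount(lab, weights=vals, minlength=k)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts
        return pd.Series(means[self.objects.index.to_numpy()], index=self.objects.index)


def default_layer_weights(stack: SceneStack) -> dict[str, float]:
    """Layer weights that make trees prominent: DSM and Green (visible
    sensor) or NIR (multispectral) weighted 1, every other layer 0."""
    weights = {name: 0.0 for name in stack.layer_names}
    weights["DSM"] = 1.0
    weights["NIR" if stack.sensor_kind == "multispectral" else "G"] = 1.0
    return weights


def _layer_dn(stack: SceneStack, name: str) -> np.ndarray:
    arr = stack.layer(name).astype(np.float64)
    if name != "DSM":
        arr = arr * _BAND_DN_SCALE
    return arr


def multiresolution_segment(stack: SceneStack, params: SegmentationParams | None = None) -> SegmentLevel:
    """Segment the stack into homogeneous objects (see module docstring)."""
    params = params or SegmentationParams()
    params.validate()
    weights = dict(params.layer_weights) if params.layer_weights is not None \
        else default_layer_weights(stack)
    for name in weights:
        stack.layer(name)  # raises BandSchemaError on unknown layers
    active = [(name, w) for name, w in weights.items() if w > 0]
    if not active:
        raise ParameterError("at least one layer weight must be > 0")

    valid = ~stack.nodata_mask
    layers = [(_layer_dn(stack, name), w) for name, w in active]
    pixmap = _merge_regions(
        [arr for arr, _ in layers], [w for _, w in layers], valid,
        params.scale, params.color_weight, params.shape_weight,
        params.smoothness_weight, params.compactness_weight,
    )
    labels = np.zeros(stack.shape, dtype=np.int32)
    labels[valid] = pixmap + 1
    all_layers = {name: _layer_dn(stack, name) for name in stack.layer_names}
    objects = build_object_table(labels, all_layers)
    return SegmentLevel(labels=labels, objects=objects, layers=all_layers)


def _pop_std(s: np.ndarray, q: np.ndarray, n: np.ndarray) -> np.ndarray:
    mean = s / n
    var = q / n - mean * mean
    return np.sqrt(np.maximum(var, 0.0))


def _merge_regions(layers, lw, valid, scale, wc, ws, wsm, wcp, chunk=2_000_000):
    """Round-based mutual-best-fitting merging. Returns per-valid-pixel
    object indices (0..K-1) in raster scan order of each object's first
    pixel.

    Works on the region adjacency graph: per-object sufficient statistics
    (n, per-layer sum / sum of squares, perimeter, bbox) are maintained
    incrementally, so rounds cost O(edges) regardless of region size.
    Fusion costs are evaluated in float64 and stored as float32; edge
    arrays are int32/float32 to keep multi-megapixel scenes within memory.
    """
    shape = valid.shape
    n_pix = int(valid.sum())
    if n_pix == 0:
        return np.zeros(0, dtype=np.int32)
    idx = np.full(shape, -1, dtype=np.int32)
    idx[valid] = np.arange(n_pix, dtype=np.int32)

    # initial 4-adjacency edge list; every adjacent pixel pair shares 1 edge unit
    h_ok = valid[:, :-1] & valid[:, 1:]
    v_ok = valid[:-1, :] & valid[1:, :]
    ea = np.concatenate([idx[:, :-1][h_ok], idx[:-1, :][v_ok]])
    eb = np.concatenate([idx[:, 1:][h_ok], idx[1:, :][v_ok]])
    shared = np.ones(ea.size, dtype=np.float32)
    del h_ok, v_ok, idx

    # per-object sufficient statistics
    n = np.ones(n_pix, dtype=np.float32)
    per = np.full(n_pix, 4.0, dtype=np.float32)
    rows, cols = np.nonzero(valid)
    rmin = rows.astype(np.float32)
    rmax = rows.astype(np.float32)
    cmin = cols.astype(np.float32)
    cmax = cols.astype(np.float32)
    del rows, cols
    sums = [arr[valid].astype(np.float64) for arr in layers]
    sqs = [v * v for v in sums]

    pixmap = np.arange(n_pix, dtype=np.int32)
    threshold = float(scale) * float(scale)

    def edge_costs():
        cost = np.empty(ea.size, dtype=np.float32)
        for start in range(0, ea.size, chunk):
            sl = slice(start, min(start + chunk, ea.size))
            a, b = ea[sl], eb[sl]
            n1 = n[a].astype(np.float64)
            n2 = n[b].astype(np.float64)
            nm = n1 + n2
            color = np.zeros(a.size, dtype=np.float64)
            for s, q, w in zip(sums, sqs, lw):
                sd1 = _pop_std(s[a], q[a], n1)
                sd2 = _pop_std(s[b], q[b], n2)
                sdm = _pop_std(s[a] + s[b], q[a] + q[b], nm)
                color += w * (nm * sdm - n1 * sd1 - n2 * sd2)
            pa_, pb_ = per[a].astype(np.float64), per[b].astype(np.float64)
            per_m = pa_ + pb_ - 2.0 * shared[sl]
            d_cmpct = per_m * np.sqrt(nm) - (pa_ * np.sqrt(n1) + pb_ * np.sqrt(n2))
            h_m = np.maximum(rmax[a], rmax[b]) - np.minimum(rmin[a], rmin[b]) + 1.0
            w_m = np.maximum(cmax[a], cmax[b]) - np.minimum(cmin[a], cmin[b]) + 1.0
            bper_m = 2.0 * (h_m + w_m)
            bper_a = 2.0 * ((rmax[a] - rmin[a] + 1.0) + (cmax[a] - cmin[a] + 1.0))
            bper_b = 2.0 * ((rmax[b] - rmin[b] + 1.0) + (cmax[b] - cmin[b] + 1.0))
            d_smooth = (nm * per_m / bper_m
                        - (n1 * pa_ / bper_a.astype(np.float64)
                           + n2 * pb_ / bper_b.astype(np.float64)))
            cost[sl] = (wc * color + ws * (wcp * d_cmpct + wsm * d_smooth)).astype(np.float32)
        return cost

    while ea.size:
        cost = edge_costs()
        admissible = cost < threshold
        if not admissible.any():
            break

        k = n.size
        best_cost = np.full(k, np.inf, dtype=np.float32)
        np.minimum.at(best_cost, ea, cost)
        np.minimum.at(best_cost, eb, cost)
        best_nb = np.full(k, k, dtype=np.int32)
        at_min = cost == best_cost[ea]
        np.minimum.at(best_nb, ea[at_min], eb[at_min])
        at_min = cost == best_cost[eb]
        np.minimum.at(best_nb, eb[at_min], ea[at_min])
        mutual = admissible & (best_nb[ea] == eb) & (best_nb[eb] == ea)
        if not mutual.any():
            # merge only the single globally cheapest admissible edge
            cand = np.flatnonzero(admissible)
            order = np.lexsort((eb[cand], ea[cand], cost[cand]))
            mutual = np.zeros(ea.size, dtype=bool)
            mutual[cand[order[0]]] = True
        del best_cost, best_nb, at_min, cost, admissible

        lo = np.minimum(ea[mutual], eb[mutual])
        hi = np.maximum(ea[mutual], eb[mutual])
        sh_pair = shared[mutual]
        parent = np.arange(k, dtype=np.int32)
        parent[hi] = lo  # disjoint pairs: one-level union suffices
        is_root = parent == np.arange(k, dtype=np.int32)
        lut = (np.cumsum(is_root, dtype=np.int64) - 1).astype(np.int32)[parent]
        root_idx = np.flatnonzero(is_root)
        tgt = lut[lo]  # distinct targets, since pairs are disjoint

        # absorb each hi object into its lo partner (gather + indexed update)
        n_hi = n[hi]
        n = n[root_idx]
        n[tgt] += n_hi
        per_hi = per[hi]
        per = per[root_idx]
        per[tgt] += per_hi - 2.0 * sh_pair
        rmin_hi = rmin[hi]
        rmin = rmin[root_idx]
        rmin[tgt] = np.minimum(rmin[tgt], rmin_hi)
        rmax_hi = rmax[hi]
        rmax = rmax[root_idx]
        rmax[tgt] = np.maximum(rmax[tgt], rmax_hi)
        cmin_hi = cmin[hi]
        cmin = cmin[root_idx]
        cmin[tgt] = np.minimum(cmin[tgt], cmin_hi)
        cmax_hi = cmax[hi]
        cmax = cmax[root_idx]
        cmax[tgt] = np.maximum(cmax[tgt], cmax_hi)
        for li in range(len(sums)):
            donor = sums[li][hi]
            sums[li] = sums[li][root_idx]
            sums[li][tgt] += donor
            donor = sqs[li][hi]
            sqs[li] = sqs[li][root_idx]
            sqs[li][tgt] += donor

        k2 = root_idx.size
        pixmap = lut[pixmap]
        # contract the adjacency graph, summing shared boundaries of
        # edges that became parallel
        na, nb = lut[ea], lut[eb]
        keep = na != nb
        lo_e = np.minimum(na[keep], nb[keep]).astype(np.int64)
        hi_e = np.maximum(na[keep], nb[keep]).astype(np.int64)
        sh = shared[keep]
        key = lo_e * np.int64(k2) + hi_e
        del na, nb, keep, lo_e, hi_e
        order = np.argsort(key)
        key = key[order]
        sh = sh[order]
        if key.size:
            boundary = np.empty(key.size, dtype=bool)
            boundary[0] = True
            np.not_equal(key[1:], key[:-1], out=boundary[1:])
            starts = np.flatnonzero(boundary)
            shared = np.add.reduceat(sh, starts)
            ea = (key[starts] // k2).astype(np.int32)
            eb = (key[starts] % k2).astype(np.int32)
        else:
            ea = np.zeros(0, dtype=np.int32)
            eb = np.zeros(0, dtype=np.int32)
            shared = np.zeros(0, dtype=np.float32)

    # compact ids in raster-scan order of each object's first pixel
    k = n.size
    first = np.full(k, np.iinfo(np.int64).max)
    np.minimum.at(first, pixmap, np.arange(n_pix, dtype=np.int64))
    order = np.argsort(first)
    remap = np.empty(k, dtype=np.int32)
    remap[order] = np.arange(k, dtype=np.int32)
    return remap[pixmap]


def build_object_table(labels: np.ndarray, layers: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Recompute the object table (counts, stats, perimeter, bbox,
    neighbours) directly from a label raster — the ground truth for all
    object statistics."""
    valid = labels > 0
    lab = labels[valid].astype(np.int64)
    if lab.size == 0:
        cols = ["pixel_count", "perimeter_px", "row_min", "row_max", "col_min",
                "col_max", "neighbors", "parent_id"]
        for name in layers:
            cols += [f"mean_{name}", f"std_{name}"]
        return pd.DataFrame(columns=cols).rename_axis("object_id")
    k = int(lab.max()) + 1
    counts = np.bincount(lab, minlength=k)
    ids = np.flatnonzero(counts)

    data: dict[str, np.ndarray] = {"pixel_count": counts[ids]}
    for name, arr in layers.items():
        vals = arr[valid].astype(np.float64)
        s = np.bincount(lab, weights=vals, minlength=k)
        q = np.bincount(lab, weights=vals * vals, minlength=k)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s / counts
            var = q / counts - mean * mean
        data[f"mean_{name}"] = mean[ids]
        data[f"std_{name}"] = np.sqrt(np.maximum(var, 0.0))[ids]

    # perimeter: 4*n minus 2 per internal same-label adjacency
    internal = np.zeros(k, dtype=np.int64)
    pair_sets = []
    for sl_a, sl_b in (
        (np.s_[:, :-1], np.s_[:, 1:]),
        (np.s_[:-1, :], np.s_[1:, :]),
    ):
        a, b = labels[sl_a].ravel(), labels[sl_b].ravel()
        both = (a > 0) & (b > 0)
        a, b = a[both].astype(np.int64), b[both].astype(np.int64)
        same = a == b
        internal += np.bincount(a[same], minlength=k)
        diff = ~same
        pair_sets.append((a[diff], b[diff]))
    perimeter = 4 * counts - 2 * internal
    data["perimeter_px"] = perimeter[ids]

    rows_idx, cols_idx = np.nonzero(valid)
    for stat, src, red, init in (
        ("row_min", rows_idx, np.minimum, np.iinfo(np.int64).max),
        ("row_max", rows_idx, np.maximum, -1),
        ("col_min", cols_idx, np.minimum, np.iinfo(np.int64).max),
        ("col_max", cols_idx, np.maximum, -1),
    ):
        acc = np.full(k, init, dtype=np.int64)
        red.at(acc, lab, src)
        data[stat] = acc[ids]

    neighbors: dict[int, set[int]] = {int(i): set() for i in ids}
    if pair_sets:
        a = np.concatenate([p[0] for p in pair_sets])
        b = np.concatenate([p[1] for p in pair_sets])
        uniq = np.unique(np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1), axis=0) \
            if a.size else np.zeros((0, 2), dtype=np.int64)
        for x, y in uniq:
            neighbors[int(x)].add(int(y))
            neighbors[int(y)].add(int(x))
    df = pd.DataFrame(data, index=pd.Index(ids, name="object_id"))
    df["neighbors"] = [frozenset(neighbors[int(i)]) for i in ids]
    df["parent_id"] = pd.array([pd.NA] * len(ids), dtype="Int64")
    return df


def build_hierarchy_level(base: SegmentLevel, merge_groups: Mapping[int, int]) -> SegmentLevel:
    """Create the upper level of the hierarchy by unioning base objects.

    ``merge_groups`` maps base object id -> group id; unassigned base
    objects carry no upper-level object. Upper-level statistics are
    recomputed from pixels, and the ``parent_id`` of grouped base objects
    is set in place.
    """
    base_ids = set(int(i) for i in base.objects.index)
    for bid in merge_groups:
        if int(bid) not in base_ids:
            raise KeyError(f"merge_groups references unknown base object {bid}")
    group_ids = sorted(set(merge_groups.values()))
    group_to_upper = {g: i + 1 for i, g in enumerate(group_ids)}
    max_label = int(base.labels.max())
    lut = np.zeros(max_label + 1, dtype=np.int32)
    for bid, gid in merge_groups.items():
        lut[int(bid)] = group_to_upper[gid]
    upper_labels = lut[base.labels]
    objects = build_object_table(upper_labels, base.layers)
    parent = pd.array(
        [group_to_upper[merge_groups[int(i)]] if int(i) in merge_groups else pd.NA
         for i in base.objects.index],
        dtype="Int64",
    )
    base.objects["parent_id"] = parent
    return SegmentLevel(labels=upper_labels, objects=objects, layers=base.layers)
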