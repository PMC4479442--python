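import numpy as np
import pytest

from orchard3d.classify import (BARE_SOIL, HERBACEOUS, TREE, classify_vegetation,
                                object_height, otsu_threshold, remove_herbaceous)
from orchard3d.errors import DegenerateDistributionError
from orchard3d.spectral import IndexLayer, excess_green
from orchard3d.synthetic import GRASS, TREE_CROWN, generate_orchard, preset_config

from conftest import level_from_labels, make_stack


def brute_force_otsu(values, weights):
    """Independent oracle: exhaustive search over all 256 bin edges for the
    split maximising the weighted between-class variance."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    edges = np.linspace(values.min(), values.max(), 257)
    best_t, best_v = None, -1.0
    for t in edges[1:-1]:
        lo = values < t
        w0, w1 = weights[lo].sum(), weights[~lo].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = np.average(values[lo], weights=weights[lo])
        mu1 = np.average(values[~lo], weights=weights[~lo])
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_class_threshold_strictly_separates(self):
        t = otsu_threshold([0.1, 0.9], [50, 50])
        assert 0.1 < t <= 0.9

    def test_matches_bruteforce_on_bimodal_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 200
            vals = np.concatenate([rng.normal(0.05, 0.02, n // 2),
                                   rng.normal(0.4, 0.05, n // 2)])
            w = rng.integers(1, 500, size=n).astype(float)
            assert otsu_threshold(vals, w) == pytest.approx(
                brute_force_otsu(vals, w), abs=1e-12)

    def test_constant_values_raise(self):
        with pytest.raises(DegenerateDistributionError):
            otsu_threshold([0.3, 0.3, 0.3], [1, 1, 1])
        with pytest.raises(DegenerateDistributionError):
            otsu_threshold([0.3], [5])


class TestClassifyVegetation:
    def test_noiseless_scene_matches_truth_classes(self):
        cfg = preset_config("single_tree_7x7", gsd=0.05, seed=2, n_rows=2, n_cols=2,
                            noise_dn=0.0, dsm_noise=0.0, grass_fraction=0.0)
        scene, truth = generate_orchard(cfg)
        from orchard3d.segmentation import multiresolution_segment
        level = multiresolution_segment(scene)
        classes = classify_vegetation(level, excess_green(scene))
        veg_lut = np.zeros(int(level.labels.max()) + 1, dtype=bool)
        veg_lut[classes.ids_of(TREE)] = True
        veg_px = veg_lut[level.labels]
        crown = truth.class_mask == TREE_CROWN
        assert (veg_px & crown).sum() / crown.sum() >= 0.99
        soil = truth.class_mask == 0
        assert (~veg_px & soil).sum() / soil.sum() >= 0.99

    def test_all_soil_scene_surfaces_degenerate_error(self):
        g = np.full((12, 12), 100 / 255, dtype=np.float32)
        stack = make_stack({"R": g, "G": g, "B": g}, np.zeros((12, 12)))
        from orchard3d.segmentation import SegmentationParams, multiresolution_segment
        level = multiresolution_segment(stack, SegmentationParams(scale=100.0))
        with pytest.raises(DegenerateDistributionError):
            classify_vegetation(level, excess_green(stack))

    def test_threshold_applied_to_object_means_not_pixels(self):
        # object 1 is half-bright / half-dark, object 2 dark, object 3 bright:
        # the mixed object is classified once, as a unit
        labels = np.ones((4, 12), dtype=np.int32)
        labels[:, 4:8] = 2
        labels[:, 8:] = 3
        index_vals = np.zeros((4, 12))
        index_vals[:, :2] = 0.8   # bright half of object 1
        index_vals[:, 8:] = 0.8
        layers = {"G": index_vals}
        level = level_from_labels(labels, layers)
        index = IndexLayer(values=index_vals, index_kind="ExG",
                           nodata_mask=np.zeros((4, 12), bool))
        classes = classify_vegetation(level, index)
        assert classes.object_class.loc[3] == TREE
        assert classes.object_class.loc[2] == BARE_SOIL
        # the mixed object gets a single label despite pixel-level bimodality
        assert classes.object_class.loc[1] in (TREE, BARE_SOIL)
        veg_like = classes.object_class.loc[1]
        assert (classes.object_class == veg_like).sum() in (1, 2)


def _two_object_level(dsm, obj_rows=(4, 8), obj_cols=(4, 8)):
    """One square vegetation object embedded in a soil background."""
    labels = np.ones(dsm.shape, dtype=np.int32)
    labels[obj_rows[0]:obj_rows[1], obj_cols[0]:obj_cols[1]] = 2
    level = level_from_labels(labels, {"DSM": dsm})
    index_vals = np.where(labels == 2, 0.5, 0.0)
    index = IndexLayer(index_vals, "ExG", np.zeros(dsm.shape, bool))
    classes = classify_vegetation(level, index)
    assert classes.object_class.loc[2] == TREE
    return level, classes


class TestObjectHeight:
    def test_flat_terrain_baseline(self):
        dsm = np.full((12, 12), 100.0)
        dsm[4:8, 4:8] = 103.0
        level, classes = _two_object_level(dsm)
        classes = object_height(level, dsm, classes, ring_px=3)
        assert classes.object_height.loc[2] == pytest.approx(3.0, abs=1e-9)
        assert classes.baseline_elev.loc[2] == pytest.approx(100.0)

    def test_tilted_plane_local_baseline_removes_slope(self):
        # flat-topped 3 m object over a 10 % slope; gsd 0.1 m; ring 3 px ->
        # tolerance ring*gsd*slope = 0.03 m (median ring soil sits at the
        # object's centerline)
        gsd, slope = 0.1, 0.10
        cols = np.arange(24) * gsd
        terrain = slope * cols[None, :].repeat(24, axis=0)
        dsm = terrain.copy()
        center_elev = terrain[12, 11:13].mean()
        dsm[8:16, 8:16] = center_elev + 3.0
        labels = np.ones((24, 24), dtype=np.int32)
        labels[8:16, 8:16] = 2
        level = level_from_labels(labels, {"DSM": dsm})
        index = IndexLayer(np.where(labels == 2, 0.5, 0.0), "ExG",
                           np.zeros((24, 24), bool))
        classes = classify_vegetation(level, index)
        classes = object_height(level, dsm, classes, ring_px=3)
        assert classes.object_height.loc[2] == pytest.approx(3.0, abs=3 * gsd * slope + 1e-6)

    def test_dsm_translation_invariance(self):
        dsm = np.full((12, 12), 100.0)
        dsm[4:8, 4:8] = 103.0
        level, classes = _two_object_level(dsm)
        classes = object_height(level, dsm, classes, ring_px=3)
        level2, classes2 = _two_object_level(dsm + 57.0)
        classes2 = object_height(level2, dsm + 57.0, classes2, ring_px=3)
        assert classes2.object_height.loc[2] == pytest.approx(
            classes.object_height.loc[2], abs=1e-9)
        np.testing.assert_allclose(
            np.nan_to_num(classes2.pixel_height), np.nan_to_num(classes.pixel_height),
            atol=1e-9)

    def test_heights_clamped_at_zero(self):
        dsm = np.full((12, 12), 100.0)
        dsm[4:8, 4:8] = 99.0  # vegetation below its baseline: noise, not canopy
        level, classes = _two_object_level(dsm)
        classes = object_height(level, dsm, classes, ring_px=3)
        assert classes.object_height.loc[2] == 0.0

    def test_no_soil_anywhere_records_failure(self):
        dsm = np.full((8, 8), 100.0)
        labels = np.ones((8, 8), dtype=np.int32)
        level = level_from_labels(labels, {"DSM": dsm})
        from orchard3d.classify import ClassMap
        import pandas as pd
        classes = ClassMap(
            object_class=pd.Series({1: TREE}),
            object_height=pd.Series({1: np.nan}),
            baseline_elev=pd.Series({1: np.nan}),
        )
        classes = object_height(level, dsm, classes, ring_px=2, max_ring_factor=2)
        assert 1 in classes.baseline_failed
        classes = remove_herbaceous(classes)
        assert classes.object_class.loc[1] == HERBACEOUS


class TestRemoveHerbaceous:
    def test_height_cut(self):
        import pandas as pd
        from orchard3d.classify import ClassMap
        classes = ClassMap(
            object_class=pd.Series({1: TREE, 2: TREE, 3: BARE_SOIL}),
            object_height=pd.Series({1: 0.2, 2: 3.0, 3: np.nan}),
            baseline_elev=pd.Series({1: 0.0, 2: 0.0, 3: np.nan}),
        )
        classes = remove_herbaceous(classes, min_tree_height=0.5)
        assert classes.object_class.loc[1] == HERBACEOUS
        assert classes.object_class.loc[2] == TREE
        assert classes.object_class.loc[3] == BARE_SOIL

    def test_grass_patches_removed_on_synthetic_scene(self, small_result, small_scene):
        _, truth = small_scene
        classes = small_result.classes
        level = small_result.level
        # every crown-truth pixel majority-maps to tree objects, grass to non-tree
        tree_lut = np.zeros(int(level.labels.max()) + 1, dtype=bool)
        tree_lut[classes.ids_of(TREE)] = True
        tree_px = tree_lut[level.labels]
        crown = truth.class_mask == TREE_CROWN
        grass = truth.class_mask == GRASS
        assert (tree_px & crown).sum() / crown.sum() >= 0.98
        assert (tree_px & grass).sum() / max(grass.sum(), 1) <= 0.05
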