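import numpy as np
import pandas as pd
import pytest

from orchard3d.classify import BARE_SOIL, TREE, ClassMap
from orchard3d.errors import EmptySummaryError, FeatureError
from orchard3d.features import (TreeRecord, compute_tree_records, entity_metrics,
                                merge_tree_entities, summarize_field)
from orchard3d.georef import GridTransform
from orchard3d.synthetic import generate_orchard, preset_config, rasterize_truth
from orchard3d.validation import pair_by_position

from conftest import level_from_labels


def _entity_level(height_map, gsd=0.1):
    """A single tree entity occupying the pixels where height_map is finite."""
    heights = np.asarray(height_map, dtype=np.float32)
    labels = np.where(np.isfinite(heights), 1, 0).astype(np.int32)
    level = level_from_labels(labels, {"DSM": np.nan_to_num(heights)})
    classes = ClassMap(
        object_class=pd.Series({1: TREE}),
        object_height=pd.Series({1: float(np.nanmax(heights))}),
        baseline_elev=pd.Series({1: 0.0}),
        pixel_height=heights,
    )
    transform = GridTransform.from_origin(0.0, 100.0, gsd, gsd)
    return level, classes, transform


class TestEntityMetrics:
    def test_single_pixel_integration(self):
        h = np.full((3, 3), np.nan)
        h[1, 1] = 2.0
        level, classes, transform = _entity_level(h, gsd=0.1)
        rec = entity_metrics(1, level, classes, transform)
        assert rec.projected_area == pytest.approx(0.01)
        assert rec.volume == pytest.approx(0.02)
        assert rec.height == pytest.approx(2.0)
        assert (rec.x, rec.y) == pytest.approx((0.15, 100.0 - 0.15))

    def test_half_ellipsoid_recovery(self):
        # rx = ry = 1.5 m, apex 2.5 m at gsd 0.05 m
        rx = ry = 1.5
        apex = 2.5
        gsd = 0.05
        n = int(4.0 / gsd)
        c = n / 2 * gsd
        y, x = np.mgrid[0:n, 0:n] * gsd + gsd / 2
        d2 = ((x - c) / rx) ** 2 + ((y - c) / ry) ** 2
        h = np.where(d2 < 1, apex * np.sqrt(np.clip(1 - d2, 0, None)), np.nan)
        level, classes, transform = _entity_level(h, gsd=gsd)
        rec = entity_metrics(1, level, classes, transform)
        assert rec.projected_area == pytest.approx(np.pi * rx * ry, rel=0.02)
        assert rec.height == pytest.approx(apex, abs=0.05)
        assert rec.volume == pytest.approx(2 / 3 * np.pi * rx * ry * apex, rel=0.02)
        assert rec.length_axis >= rec.width_axis
        assert rec.length_axis == pytest.approx(2 * rx, rel=0.1)

    def test_record_carries_full_column_set(self):
        h = np.full((3, 3), np.nan)
        h[1, 1] = 1.0
        level, classes, transform = _entity_level(h)
        rec = entity_metrics(1, level, classes, transform)
        assert set(rec.to_dict()) == {
            "tree_id", "x", "y", "length_axis", "width_axis",
            "projected_area", "height", "volume",
        }

    def test_entity_without_heights_raises(self):
        h = np.full((3, 3), np.nan)
        h[1, 1] = 1.0
        level, classes, transform = _entity_level(h)
        classes.pixel_height = np.full((3, 3), np.nan, dtype=np.float32)
        with pytest.raises(FeatureError):
            entity_metrics(1, level, classes, transform)

    def test_volume_additivity_under_arbitrary_splits(self):
        rng = np.random.default_rng(13)
        h = rng.uniform(0.5, 3.0, size=(10, 10)).astype(np.float32)
        level, classes, transform = _entity_level(h, gsd=0.1)
        whole = entity_metrics(1, level, classes, transform)
        split = np.asarray(rng.integers(0, 2, size=(10, 10)), dtype=np.int32) + 1
        level2 = level_from_labels(split, {"DSM": h.astype(float)})
        classes.pixel_height = h
        parts = [entity_metrics(i, level2, classes, transform) for i in (1, 2)]
        assert sum(p.volume for p in parts) == pytest.approx(whole.volume, rel=1e-9)

    def test_volume_bounded_by_area_times_height(self, small_result):
        for rec in small_result.records:
            assert rec.volume <= rec.projected_area * rec.height * (1 + 1e-9)
            assert rec.length_axis >= rec.width_axis > 0
            assert rec.projected_area > 0 and rec.height >= 0


class TestMergeTreeEntities:
    def test_isolated_crowns_one_entity_each(self, small_result, small_scene):
        _, truth = small_scene
        assert len(small_result.records) == len(truth.trees)

    def test_row_scene_one_entity_per_row(self, row_result, row_scene):
        _, truth = row_scene
        # 4 rows of touching crowns -> 4 entities
        assert len(row_result.records) == 4

    def test_zero_tree_objects_valid_empty_set(self):
        labels = np.ones((6, 6), dtype=np.int32)
        level = level_from_labels(labels, {"DSM": np.zeros((6, 6))})
        classes = ClassMap(
            object_class=pd.Series({1: BARE_SOIL}),
            object_height=pd.Series({1: np.nan}),
            baseline_elev=pd.Series({1: np.nan}),
        )
        entities = merge_tree_entities(level, classes)
        assert len(entities.objects) == 0
        records = compute_tree_records(entities, classes,
                                       GridTransform.from_origin(0, 10, 0.1, 0.1))
        assert records == []

    def test_min_area_filter_drops_specks(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:12, 2:12] = 1   # 100 px = 1 m² at gsd 0.1
        labels[15, 15] = 2       # single speck, 0.01 m²
        labels[labels == 0] = 3
        level = level_from_labels(labels, {"DSM": np.zeros((20, 20))})
        classes = ClassMap(
            object_class=pd.Series({1: TREE, 2: TREE, 3: BARE_SOIL}),
            object_height=pd.Series({1: 2.0, 2: 2.0, 3: np.nan}),
            baseline_elev=pd.Series({1: 0.0, 2: 0.0, 3: np.nan}),
        )
        entities = merge_tree_entities(level, classes, min_entity_area_m2=0.1, gsd=0.1)
        assert len(entities.objects) == 1


class TestPipelineAccuracy:
    def test_grid_scene_recovers_per_tree_features(self, small_result, small_scene):
        _, truth = small_scene
        _, ref = rasterize_truth(truth)
        est_xy = [(r.x, r.y) for r in small_result.records]
        pairs = pair_by_position(est_xy, ref[["x", "y"]].to_numpy(), max_dist=2.0)
        assert len(pairs) == len(ref)
        for i, j in pairs:
            rec = small_result.records[i]
            assert rec.height == pytest.approx(ref["height"].iloc[j], abs=0.15)
            assert rec.projected_area == pytest.approx(
                ref["projected_area"].iloc[j], rel=0.08)
            assert rec.volume == pytest.approx(ref["volume"].iloc[j], rel=0.12)


class TestSummarizeField:
    def _recs(self, heights, xs=None):
        xs = xs or [7.0 * i for i in range(len(heights))]
        return [
            TreeRecord(tree_id=i + 1, x=x, y=0.0, length_axis=3.0, width_axis=2.0,
                       projected_area=5.0, height=h, volume=8.0)
            for i, (h, x) in enumerate(zip(heights, xs))
        ]

    def test_mean_and_count(self):
        s = summarize_field(self._recs([2.0, 3.0, 4.0]))
        assert s.n_trees == 3
        assert s.mean_height == pytest.approx(3.0)

    def test_grid_spacing_recovered(self, small_result):
        s = summarize_field(small_result.records, spacing_hint=7.0)
        assert s.mean_nn_spacing == pytest.approx(7.0, rel=0.02)

    def test_single_record_flagged(self):
        s = summarize_field(self._recs([2.5]))
        assert s.single_sample
        assert s.std_height == 0.0

    def test_empty_raises(self):
        with pytest.raises(EmptySummaryError):
            summarize_field([])
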