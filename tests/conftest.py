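import numpy as np
import pytest

from orchard3d.georef import GridTransform
from orchard3d.pipeline import run_pipeline
from orchard3d.scene_io import SceneStack
from orchard3d.segmentation import SegmentLevel, build_object_table
from orchard3d.synthetic import generate_orchard, preset_config


def make_stack(bands, dsm, gsd=0.1, sensor_kind="visible", nodata_mask=None,
               origin=(1000.0, 2000.0)):
    """Hand-built SceneStack from plain arrays (bands already in [0, 1])."""
    dsm = np.asarray(dsm, dtype=np.float64)
    transform = GridTransform.from_origin(origin[0], origin[1], gsd, gsd)
    return SceneStack(
        bands={k: np.asarray(v, dtype=np.float32) for k, v in bands.items()},
        dsm=dsm, transform=transform, crs_epsg=32630,
        sensor_kind=sensor_kind, nodata_mask=nodata_mask,
    )


def level_from_labels(labels, layers):
    """SegmentLevel with its object table recomputed from a label raster."""
    labels = np.asarray(labels, dtype=np.int32)
    layers = {k: np.asarray(v, dtype=np.float64) for k, v in layers.items()}
    return SegmentLevel(labels=labels, objects=build_object_table(labels, layers),
                        layers=layers)


@pytest.fixture(scope="session")
def small_cfg():
    # 3x3 single-tree block at 5 cm GSD: fast but carries every scene feature
    return preset_config("single_tree_7x7", gsd=0.05, seed=7, n_rows=3, n_cols=3)


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    return generate_orchard(small_cfg)


@pytest.fixture(scope="session")
def small_result(small_scene):
    scene, _ = small_scene
    return run_pipeline(scene)


@pytest.fixture(scope="session")
def row_scene():
    cfg = preset_config("tree_row_3.75x1.3", gsd=0.04, seed=3, n_cols=4, n_rows=10)
    return generate_orchard(cfg)


@pytest.fixture(scope="session")
def row_result(row_scene):
    scene, _ = row_scene
    return run_pipeline(scene)
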