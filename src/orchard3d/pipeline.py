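"""End-to-end orchestration: index -> segment -> classify -> heights ->
merge -> metrics -> export."""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import classify, features, spectral
from .classify import ClassMap
from .features import FieldSummary, TreeRecord
from .scene_io import SceneStack, write_entities
from .segmentation import SegmentationParams, SegmentLevel, multiresolution_segment

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the workflow produces for one scene."""

    scene: SceneStack
    level: SegmentLevel
    classes: ClassMap
    entities: SegmentLevel
    records: list[TreeRecord]
    summary: FieldSummary | None

    @property
    def tree_mask(self) -> np.ndarray:
        """Boolean raster of pixels belonging to a tree entity."""
        return self.entities.labels > 0

    def footprints(self):
        return features.entity_footprints(self.entities, self.scene.transform)


def run_pipeline(
    scene: SceneStack,
    params: SegmentationParams | None = None,
    min_tree_height: float = 0.5,
    ring_px: int = 5,
    min_entity_area_m2: float = 0.1,
    height_stat: str = "max",
    axes_method: str = "obb",
) -> PipelineResult:
    """Run the full object-based workflow on a loaded scene."""
    t0 = time.perf_counter()
    index = spectral.vegetation_index(scene)
    log.info("index (%s) computed in %.1fs", index.index_kind, time.perf_counter() - t0)

    t0 = time.perf_counter()
    level = multiresolution_segment(scene, params)
    log.info("segmentation: %d objects in %.1fs", len(level.objects), time.perf_counter() - t0)

    t0 = time.perf_counter()
    classes = classify.classify_vegetation(level, index)
    classes = classify.object_height(level, scene.dsm, classes, ring_px=ring_px,
                                     height_stat=height_stat)
    classes = classify.remove_herbaceous(classes, min_tree_height=min_tree_height)
    log.info("classification in %.1fs (index threshold %.4f)",
             time.perf_counter() - t0, classes.threshold)

    t0 = time.perf_counter()
    entities = features.merge_tree_entities(level, classes,
                                            min_entity_area_m2=min_entity_area_m2,
                                            gsd=scene.gsd)
    records = features.compute_tree_records(entities, classes, scene.transform,
                                            height_stat=height_stat,
                                            axes_method=axes_method)
    summary = features.summarize_field(records) if records else None
    log.info("%d tree entities measured in %.1fs", len(records), time.perf_counter() - t0)
    return PipelineResult(scene=scene, level=level, classes=classes,
                          entities=entities, records=records, summary=summary)


def export_result(result: PipelineResult, vector_path, table_path) -> None:
    """Write the entity footprints (GeoJSON) and attribute table (CSV)."""
    write_entities(result.records, result.footprints(), vector_path, table_path)
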