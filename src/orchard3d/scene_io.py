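"""Reading, aligning and writing the raster and vector artifacts of the pipeline.

GeoTIFFs are read and written with :mod:`tifffile`, carrying the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the
GDAL nodata convention. Only north-up rasters in a projected metric CRS are
supported; anything else fails loudly rather than being resampled silently.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile

from .errors import BandSchemaError, CrsUnitError, SceneAlignmentError
from .georef import GridTransform

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

VISIBLE_BANDS = ("R", "G", "B")
#: default band order of the 6-channel multispectral camera (two red channels)
MULTISPEC_BANDS = ("B", "G", "R", "R700", "RE", "NIR")

#: CSV column order of the per-tree output table
TABLE_COLUMNS = (
    "tree_id", "x", "y", "length_axis", "width_axis",
    "projected_area", "height", "volume",
)


@dataclass
class SceneStack:
    """Co-registered spectral bands + DSM with shared georeferencing.

    Bands are stored as float32 in [0, 1] (8-bit DN divided by 255); the DSM
    is elevation in metres. ``nodata_mask`` is True where any layer is invalid.
    """

    bands: dict[str, np.ndarray]
    dsm: np.ndarray
    transform: GridTransform
    crs_epsg: int
    sensor_kind: str  # "visible" | "multispectral"
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()} | {self.dsm.shape}
        if len(shapes) != 1:
            raise SceneAlignmentError(f"layers have differing shapes: {shapes}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.dsm.shape, dtype=bool)
        required = {"visible": {"R", "G", "B"}, "multispectral": {"R", "NIR"}}
        missing = required.get(self.sensor_kind, set()) - set(self.bands)
        if self.sensor_kind not in required:
            raise BandSchemaError(f"unknown sensor_kind {self.sensor_kind!r}")
        if missing:
            raise BandSchemaError(
                f"sensor_kind={self.sensor_kind!r} requires bands {sorted(missing)}"
            )
        valid = ~self.nodata_mask
        if not np.all(np.isfinite(self.dsm[valid])):
            raise SceneAlignmentError("DSM contains non-finite values outside nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dsm.shape

    @property
    def gsd(self) -> float:
        """Ground sample distance in m/pixel (square pixels assumed)."""
        sx, sy = self.transform.pixel_size
        return (sx + sy) / 2.0

    def layer(self, name: str) -> np.ndarray:
        """Return a band by name, or the DSM for name == 'DSM'."""
        if name == "DSM":
            return self.dsm
        try:
            return self.bands[name]
        except KeyError:
            raise BandSchemaError(f"no such layer: {name!r}") from None

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self.bands) + ("DSM",)


def _geokey_directory(epsg: int, model_type: int = 1) -> tuple[int, ...]:
    # header: version, rev, minor, number of keys
    keys = [
        (1024, 0, 1, model_type),   # GTModelType: 1 projected, 2 geographic
        (1025, 0, 1, 1),            # GTRasterType: PixelIsArea
        (3072, 0, 1, int(epsg)),    # ProjectedCSType
        (3076, 0, 1, 9001),         # ProjLinearUnits: metre
    ]
    if model_type == 2:
        keys = [keys[0], keys[1], (2048, 0, 1, int(epsg))]
    flat = [1, 1, 0, len(keys)]
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def write_geotiff(
    path,
    data: np.ndarray,
    transform: GridTransform,
    epsg: int = 32630,
    nodata: float | None = None,
    geographic: bool = False,
) -> None:
    """Write a (H, W) or (H, W, C) array as a tiled GeoTIFF."""
    sx, sy = transform.pixel_size
    geokeys = _geokey_directory(epsg, 2 if geographic else 1)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (sx, sy, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
    ]
    if nodata is not None:
        text = str(nodata)
        extratags.append((_GDAL_NODATA, "s", len(text) + 1, text))
    photometric = "rgb" if data.ndim == 3 and data.shape[2] == 3 else "minisblack"
    tifffile.imwrite(
        str(path), data, photometric=photometric,
        planarconfig="contig" if data.ndim == 3 else None,
        extratags=extratags,
    )


def read_geotiff(path):
    """Read a GeoTIFF written by :func:`write_geotiff` (or any north-up GeoTIFF).

    Returns ``(array, transform, epsg, nodata)``. Raises
    :class:`CrsUnitError` for geographic (degree-unit) rasters.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags.get(_MODEL_PIXEL_SCALE)
        tie = tags.get(_MODEL_TIEPOINT)
        if scale is None or tie is None:
            raise SceneAlignmentError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = scale.value[0], scale.value[1]
        west, north = tie.value[3], tie.value[4]
        transform = GridTransform.from_origin(west, north, sx, sy)
        epsg = 0
        geokeys = tags.get(_GEO_KEY_DIRECTORY)
        if geokeys is not None:
            vals = list(geokeys.value)
            nkeys = vals[3]
            for i in range(nkeys):
                key_id, _, _, value = vals[4 + 4 * i: 8 + 4 * i]
                if key_id == 1024 and value == 2:
                    raise CrsUnitError(
                        f"{path}: geographic CRS (degrees); a metric projected CRS is required"
                    )
                if key_id in (3072, 2048):
                    epsg = value
        nodata_tag = tags.get(_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else None
    return data, transform, epsg, nodata


def _normalize_dn(band: np.ndarray) -> np.ndarray:
    """8/16-bit DN to float32 reflectance-like values in [0, 1]."""
    if band.dtype == np.uint8:
        return band.astype(np.float32) / 255.0
    if band.dtype == np.uint16:
        return band.astype(np.float32) / 65535.0
    return band.astype(np.float32)


def load_scene(
    ortho_path,
    dsm_path=None,
    sensor_kind: str = "visible",
    band_names: Sequence[str] | None = None,
) -> SceneStack:
    """Load an orthomosaic (+ DSM) pair into a :class:`SceneStack`.

    The DSM may live in its own GeoTIFF (``dsm_path``) or, following the
    multi-layer-file convention, as the last channel of the orthomosaic.
    Layers must share the pixel grid within half a pixel; no resampling is
    attempted.
    """
    ortho, transform, epsg, ortho_nodata = read_geotiff(ortho_path)
    if ortho.ndim == 2:
        ortho = ortho[:, :, None]
    n_chan = ortho.shape[2]

    if dsm_path is not None:
        dsm, dsm_transform, dsm_epsg, dsm_nodata = read_geotiff(dsm_path)
        if dsm.ndim != 2:
            raise SceneAlignmentError(f"{dsm_path}: DSM must be single-band")
        if dsm.shape != ortho.shape[:2]:
            raise SceneAlignmentError(
                f"ortho {ortho.shape[:2]} and DSM {dsm.shape} shapes differ"
            )
        if not transform.almost_equals(dsm_transform):
            raise SceneAlignmentError("ortho and DSM transforms differ beyond half a pixel")
        if dsm_epsg and epsg and dsm_epsg != epsg:
            raise SceneAlignmentError(f"CRS mismatch: EPSG:{epsg} vs EPSG:{dsm_epsg}")
        band_stack = ortho
    else:
        # combined multi-layer file: last channel is the DSM
        if n_chan < 2:
            raise BandSchemaError("combined file needs >= 2 channels (bands + DSM)")
        dsm = ortho[:, :, -1]
        dsm_nodata = ortho_nodata
        band_stack = ortho[:, :, :-1]

    if band_names is None:
        defaults = {3: VISIBLE_BANDS, 6: MULTISPEC_BANDS}
        band_names = defaults.get(band_stack.shape[2])
        if band_names is None:
            raise BandSchemaError(
                f"{band_stack.shape[2]} bands: band_names must be given explicitly"
            )
    if len(band_names) != band_stack.shape[2]:
        raise BandSchemaError(
            f"{len(band_names)} band names for {band_stack.shape[2]} bands"
        )

    nodata = np.zeros(dsm.shape, dtype=bool)
    bands: dict[str, np.ndarray] = {}
    for i, name in enumerate(band_names):
        raw = band_stack[:, :, i]
        if ortho_nodata is not None and np.issubdtype(raw.dtype, np.integer):
            nodata |= raw == ortho_nodata
        bands[name] = _normalize_dn(raw)
        nodata |= ~np.isfinite(bands[name])
    dsm = dsm.astype(np.float64)
    nodata |= ~np.isfinite(dsm)
    if dsm_nodata is not None:
        nodata |= dsm == dsm_nodata
    dsm = np.where(np.isfinite(dsm), dsm, 0.0)

    return SceneStack(
        bands=bands, dsm=dsm, transform=transform,
        crs_epsg=epsg or 0, sensor_kind=sensor_kind, nodata_mask=nodata,
    )


def write_scene(scene: SceneStack, ortho_path, dsm_path) -> None:
    """Write a stack back to an (8-bit ortho, float DSM) GeoTIFF pair."""
    names = [n for n in scene.bands]
    dn = np.stack(
        [np.clip(np.rint(scene.bands[n] * 255.0), 0, 255).astype(np.uint8) for n in names],
        axis=-1,
    )
    write_geotiff(ortho_path, dn, scene.transform, scene.crs_epsg or 32630)
    dsm = scene.dsm.astype(np.float32).copy()
    nodata_val = None
    if scene.nodata_mask.any():
        nodata_val = -9999.0
        dsm[scene.nodata_mask] = nodata_val
    write_geotiff(dsm_path, dsm, scene.transform, scene.crs_epsg or 32630, nodata=nodata_val)


def write_entities(
    records: Iterable,
    polygons: Mapping[int, shapely.Geometry],
    vector_path,
    table_path,
) -> None:
    """Export per-entity footprints (GeoJSON) and the attribute table (CSV).

    ``records`` and ``polygons`` are keyed by the same tree ids; every record
    becomes one GeoJSON feature carrying the full attribute set and one CSV row.
    """
    rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    table.to_csv(table_path, index=False, float_format="%.3f")

    features = []
    for row in rows:
        tid = int(row["tree_id"])
        geom = polygons.get(tid)
        features.append(
            {
                "type": "Feature",
                "id": tid,
                "properties": {
                    k: (round(float(v), 6) if isinstance(v, (float, np.floating)) else v)
                    for k, v in row.items()
                },
                "geometry": json.loads(shapely.to_geojson(geom)) if geom is not None else None,
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(vector_path).write_text(json.dumps(collection, indent=1))


def read_entity_table(table_path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_entities`."""
    return pd.read_csv(table_path)


def geojson_polygons(vector_path) -> dict[int, shapely.Geometry]:
    """Footprint geometries from a GeoJSON file written by :func:`write_entities`."""
    collection = json.loads(Path(vector_path).read_text())
    out = {}
    for feat in collection["features"]:
        geom = feat.get("geometry")
        key = int(feat.get("id", feat["properties"].get("tree_id")))
        out[key] = shapely.from_geojson(json.dumps(geom)) if geom else None
    return out


def rasterized_area_m2(mask: np.ndarray, gsd: float) -> float:
    """Area (m²) of a boolean mask at a given ground sample distance."""
    return float(np.count_nonzero(mask)) * gsd * gsd
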