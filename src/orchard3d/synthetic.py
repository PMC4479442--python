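"""Synthetic orchard scenes with analytic ground truth.

Generates georeferenced orthomosaic + DSM pairs that carry the structure
the pipeline assumes: a planar-to-gently-undulating terrain, half-ellipsoid
tree crowns planted on a regular grid (single-tree pattern) or in touching
hedgerows (tree-row pattern), low herbaceous patches, soil/canopy spectral
contrast and additive sensor noise. Crowns are half-ellipsoids resting on
the terrain, so projected area (pi*rx*ry), apex height (h) and crown volume
((2/3)*pi*rx*ry*h) have closed forms — exactly the quantities the pipeline
estimates.

The spectral model is a per-class mean + Gaussian-noise model (not
radiative transfer): sufficient to exercise index thresholding and its
failure mode of low soil/canopy contrast. DSM noise is spatially smoothed
before being rescaled, mimicking the correlated error of photogrammetric
surface reconstruction rather than white sensor noise.

Everything is driven by one integer seed: the same config + seed gives
bit-identical rasters.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .georef import GridTransform
from .scene_io import SceneStack, write_geotiff, write_scene

#: default per-class band means (8-bit DN) per sensor kind
BAND_MEANS = {
    "visible": {
        "soil": {"R": 150, "G": 120, "B": 90},
        "canopy": {"R": 60, "G": 90, "B": 50},
        "grass": {"R": 70, "G": 110, "B": 60},
    },
    "multispectral": {
        "soil": {"B": 90, "G": 110, "R": 130, "R700": 130, "RE": 125, "NIR": 120},
        "canopy": {"B": 40, "G": 60, "R": 50, "R700": 55, "RE": 90, "NIR": 170},
        "grass": {"B": 45, "G": 70, "R": 60, "R700": 65, "RE": 95, "NIR": 150},
    },
}

#: class codes in the truth mask
SOIL, GRASS, TREE_CROWN = 0, 1, 2

#: band noise sigma (DN) of the "clean" low-altitude presets
LOW_NOISE_DN = 2.0
LOW_DSM_NOISE = 0.02


@dataclass
class OrchardConfig:
    """Parameters of a synthetic orchard scene.

    spacing is (x, y) metres between trunks; in tree_row pattern the x
    spacing separates rows and the y spacing separates trees within a row
    (crown y-radii exceed half the y spacing, so crowns touch along rows).
    Radii/height ranges are sampled uniformly per tree. Slope is (dz/dx,
    dz/dy) in m/m; undulation is a smooth low-frequency surface of the
    given amplitude. All DN values refer to the 8-bit scale.
    """

    pattern: str = "single_tree"          # "single_tree" | "tree_row"
    spacing: tuple[float, float] = (7.0, 7.0)
    n_rows: int = 6                       # trees per column (y direction)
    n_cols: int = 6                       # columns (x direction)
    crown_radius_range: tuple[float, float] = (1.4, 2.2)   # x semi-axis, m
    crown_radius_range_y: tuple[float, float] | None = None  # default: same as x
    crown_height_range: tuple[float, float] = (2.0, 4.0)   # m
    crown_gap_fraction: float = 0.0
    center_jitter: float = 0.1            # m, uniform trunk-position jitter
    terrain_slope: tuple[float, float] = (0.02, 0.0)
    undulation_amplitude: float = 0.15    # m
    undulation_wavelength: float = 30.0   # m
    grass_fraction: float = 0.05
    grass_height: float = 0.3             # m, maximum herbaceous height
    sensor_kind: str = "visible"
    gsd: float = 0.0271                   # m/pixel
    noise_dn: float = 4.0                 # band noise sigma, DN
    dsm_noise: float = 0.03               # DSM noise sigma after smoothing, m
    dsm_smooth_px: float = 1.5            # spatial correlation of DSM noise
    band_means: dict | None = None        # override BAND_MEANS[sensor_kind]
    origin: tuple[float, float] = (350000.0, 4200000.0)   # map x, y of SW corner
    epsg: int = 32630
    seed: int = 0

    def validate(self) -> None:
        if self.gsd <= 0:
            raise ConfigError("gsd must be > 0")
        if self.pattern not in ("single_tree", "tree_row"):
            raise ConfigError(f"unknown pattern {self.pattern!r}")
        rx_max = self.crown_radius_range[1]
        ry_max = (self.crown_radius_range_y or self.crown_radius_range)[1]
        if self.pattern == "single_tree":
            tol = self.center_jitter
            if 2 * rx_max + 2 * tol > self.spacing[0] or 2 * ry_max + 2 * tol > self.spacing[1]:
                raise ConfigError(
                    "single_tree crowns would overlap: radii must stay below half the spacing"
                )
        else:
            if 2 * rx_max > self.spacing[0]:
                raise ConfigError("tree_row: rows would touch across the inter-row gap")
        if self.grass_height >= self.crown_height_range[0]:
            raise ConfigError("grass height must stay below the minimum crown height")
        if not 0 <= self.crown_gap_fraction < 1:
            raise ConfigError("crown_gap_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Analytic per-tree truth plus reference rasters.

    trees: DataFrame with tree_id, x, y, rx, ry, height and the closed-form
    area (pi*rx*ry) and volume ((2/3)*pi*rx*ry*h). class_mask codes:
    0 soil, 1 grass, 2 tree crown.
    """

    trees: pd.DataFrame
    class_mask: np.ndarray
    terrain: np.ndarray
    transform: GridTransform

    @property
    def tree_mask(self) -> np.ndarray:
        return self.class_mask == TREE_CROWN


def _smooth_noise(rng, shape, sigma_px, amplitude):
    """Low-frequency noise surface with unit-free amplitude scaling."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_px)
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth * (amplitude / sd)


def generate_orchard(config: OrchardConfig, seed: int | None = None) -> tuple[SceneStack, GroundTruth]:
    """Generate a scene stack and its ground truth (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sx, sy = config.spacing
    width_m = config.n_cols * sx
    height_m = config.n_rows * sy
    w = max(int(round(width_m / config.gsd)), 8)
    h = max(int(round(height_m / config.gsd)), 8)
    x0, y0 = config.origin
    transform = GridTransform.from_origin(x0, y0 + height_m, config.gsd, config.gsd)

    cols = np.arange(w)
    rows = np.arange(h)
    px_x = x0 + (cols + 0.5) * config.gsd              # map x of pixel centers
    px_y = y0 + height_m - (rows + 0.5) * config.gsd   # map y (row 0 at top)
    X, Y = np.meshgrid(px_x, px_y)

    # terrain: plane + smooth undulation
    ax, ay = config.terrain_slope
    terrain = ax * (X - x0) + ay * (Y - y0)
    if config.undulation_amplitude > 0:
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        lam = config.undulation_wavelength
        terrain = terrain + config.undulation_amplitude * (
            np.sin(2 * np.pi * (X - x0) / lam + phx)
            * np.sin(2 * np.pi * (Y - y0) / lam + phy)
        )

    # trees on the planting lattice
    ry_range = config.crown_radius_range_y or config.crown_radius_range
    records = []
    crown_field = np.zeros((h, w))
    class_mask = np.zeros((h, w), dtype=np.uint8)
    gap_noise = None
    if config.crown_gap_fraction > 0:
        gap_noise = _smooth_noise(rng, (h, w), sigma_px=max(0.3 / config.gsd, 2), amplitude=1.0)
        gap_cut = np.quantile(gap_noise, config.crown_gap_fraction)
    tid = 0
    for i in range(config.n_cols):
        for j in range(config.n_rows):
            tid += 1
            cx = x0 + (i + 0.5) * sx + rng.uniform(-config.center_jitter, config.center_jitter)
            cy = y0 + (j + 0.5) * sy + rng.uniform(-config.center_jitter, config.center_jitter)
            rx = rng.uniform(*config.crown_radius_range)
            ry = rng.uniform(*ry_range)
            ch = rng.uniform(*config.crown_height_range)
            records.append(
                {
                    "tree_id": tid, "x": cx, "y": cy, "rx": rx, "ry": ry,
                    "height": ch,
                    "area": np.pi * rx * ry,
                    "volume": 2.0 / 3.0 * np.pi * rx * ry * ch,
                }
            )
            r0 = max(int((y0 + height_m - (cy + ry)) / config.gsd) - 1, 0)
            r1 = min(int((y0 + height_m - (cy - ry)) / config.gsd) + 2, h)
            c0 = max(int((cx - rx - x0) / config.gsd) - 1, 0)
            c1 = min(int((cx + rx - x0) / config.gsd) + 2, w)
            win = np.s_[r0:r1, c0:c1]
            dx = (X[win] - cx) / rx
            dy = (Y[win] - cy) / ry
            inside = dx * dx + dy * dy < 1.0
            if gap_noise is not None:
                inside &= gap_noise[win] >= gap_cut
            bump = np.zeros_like(dx)
            bump[inside] = ch * np.sqrt(1.0 - (dx * dx + dy * dy)[inside])
            crown_field[win] = np.maximum(crown_field[win], bump)
            class_mask[win][inside] = TREE_CROWN

    # herbaceous patches on the remaining ground
    grass_bump = np.zeros((h, w))
    if config.grass_fraction > 0:
        g = _smooth_noise(rng, (h, w), sigma_px=max(1.0 / config.gsd, 2), amplitude=1.0)
        cut = np.quantile(g, 1.0 - config.grass_fraction)
        grass = (g > cut) & (class_mask != TREE_CROWN)
        norm = g - cut
        span = norm.max()
        if span > 0:
            grass_bump[grass] = np.clip(
                config.grass_height * norm[grass] / span, 0.05, config.grass_height
            )
        class_mask[grass] = GRASS

    dsm = terrain + np.where(class_mask == TREE_CROWN, crown_field, grass_bump)
    if config.dsm_noise > 0:
        dsm = dsm + _smooth_noise(rng, (h, w), config.dsm_smooth_px, config.dsm_noise)

    # spectra: per-class means + white sensor noise, 8-bit DN
    means = config.band_means or BAND_MEANS[config.sensor_kind]
    band_names = list(next(iter(means.values())).keys())
    bands: dict[str, np.ndarray] = {}
    for name in band_names:
        lut = np.array([means["soil"][name], means["grass"][name], means["canopy"][name]],
                       dtype=np.float64)
        dn = lut[class_mask]
        if config.noise_dn > 0:
            dn = dn + rng.normal(0.0, config.noise_dn, size=dn.shape)
        bands[name] = (np.clip(np.rint(dn), 0, 255) / 255.0).astype(np.float32)

    scene = SceneStack(
        bands=bands, dsm=dsm, transform=transform,
        crs_epsg=config.epsg, sensor_kind=config.sensor_kind,
    )
    columns = ["tree_id", "x", "y", "rx", "ry", "height", "area", "volume"]
    trees = (pd.DataFrame.from_records(records) if records
             else pd.DataFrame(columns=columns)).set_index(
                 pd.Index([r["tree_id"] for r in records], name="tree_id"))
    truth = GroundTruth(
        trees=trees,
        class_mask=class_mask, terrain=terrain, transform=transform,
    )
    return scene, truth


def rasterize_truth(truth: GroundTruth) -> tuple[np.ndarray, pd.DataFrame]:
    """Reference tree mask and analytic per-tree reference records.

    Stands in for a manual delineation: the mask is the rasterized crown
    footprint, the table carries the closed-form axes/area/height/volume.
    """
    t = truth.trees
    table = pd.DataFrame(
        {
            "tree_id": t["tree_id"].to_numpy(),
            "x": t["x"].to_numpy(),
            "y": t["y"].to_numpy(),
            "length_axis": 2.0 * np.maximum(t["rx"], t["ry"]).to_numpy(),
            "width_axis": 2.0 * np.minimum(t["rx"], t["ry"]).to_numpy(),
            "projected_area": t["area"].to_numpy(),
            "height": t["height"].to_numpy(),
            "volume": t["volume"].to_numpy(),
        }
    )
    return truth.tree_mask.copy(), table


# ---------------------------------------------------------------------------
# presets mirroring the four study-field layouts

PRESETS: dict[str, OrchardConfig] = {
    # single-tree plantations at 7x7 m and 8x8 m spacing
    "single_tree_7x7": OrchardConfig(),
    "single_tree_8x8": OrchardConfig(spacing=(8.0, 8.0)),
    # hedgerow plantations: inter-row x intra-row spacing
    "tree_row_3.75x1.3": OrchardConfig(
        pattern="tree_row", spacing=(3.75, 1.3), n_cols=5, n_rows=20,
        crown_radius_range=(0.9, 1.3), crown_radius_range_y=(0.7, 0.9),
        crown_height_range=(2.0, 3.0), center_jitter=0.05,
    ),
    "tree_row_8x4": OrchardConfig(
        pattern="tree_row", spacing=(8.0, 4.0), n_cols=4, n_rows=8,
        crown_radius_range=(1.5, 2.2), crown_radius_range_y=(2.0, 2.4),
        crown_height_range=(2.5, 4.0), center_jitter=0.05,
    ),
}

#: GSDs of the flown sensor/altitude combinations (m/pixel)
SENSOR_GSD = {
    ("visible", 50): 0.0153,
    ("visible", 100): 0.0306,
    ("multispectral", 50): 0.0271,
    ("multispectral", 100): 0.0542,
}


def preset_config(
    name: str,
    *,
    gsd: float | None = None,
    seed: int | None = None,
    clean: bool = False,
    **overrides,
) -> OrchardConfig:
    """A copy of a named preset, optionally cleaned (low-noise) or overridden.

    ``clean=True`` selects the low sensor-noise variant (band sigma
    ``LOW_NOISE_DN`` DN, DSM sigma ``LOW_DSM_NOISE`` m) that emulates a
    low-altitude flight over a well-textured field.
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    kwargs = dict(overrides)
    if gsd is not None:
        kwargs["gsd"] = gsd
    if seed is not None:
        kwargs["seed"] = seed
    if clean:
        kwargs.setdefault("noise_dn", LOW_NOISE_DN)
        kwargs.setdefault("dsm_noise", LOW_DSM_NOISE)
    return replace(cfg, **kwargs)


def write_truth(
    truth: GroundTruth, mask_path, table_path, footprint_path=None, epsg: int = 32630,
) -> None:
    """Write the truth mask (GeoTIFF), the reference table (CSV) and,
    optionally, the analytic crown footprints (GeoJSON ellipses)."""
    write_geotiff(mask_path, truth.class_mask, truth.transform, epsg)
    _, table = rasterize_truth(truth)
    table.to_csv(table_path, index=False)
    if footprint_path is not None:
        import json

        import shapely
        import shapely.affinity

        features = []
        for _, t in truth.trees.iterrows():
            ellipse = shapely.affinity.scale(
                shapely.Point(t["x"], t["y"]).buffer(1.0, quad_segs=64),
                xfact=t["rx"], yfact=t["ry"], origin=(t["x"], t["y"]),
            )
            features.append({
                "type": "Feature",
                "id": int(t["tree_id"]),
                "properties": {k: float(t[k]) for k in
                               ("x", "y", "rx", "ry", "height", "area", "volume")},
                "geometry": json.loads(shapely.to_geojson(ellipse)),
            })
        Path(footprint_path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
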