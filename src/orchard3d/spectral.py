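"""Closed-form flight and spectral quantities: GSD and vegetation indices.

The ground sample distance links sensor geometry to on-ground pixel size.
The Excess Green index (ExG = 2g - r - b on chromatic coordinates) enhances
vegetation in RGB imagery; NDVI = (NIR - R)/(NIR + R) does the same where a
near-infrared band exists. Both indices are ratios of band values, so they
are invariant to any positive rescaling of the input bands — computing them
on 8-bit DN or on calibrated reflectance gives identical values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BandSchemaError, ParameterError
from .scene_io import SceneStack


@dataclass(frozen=True)
class FlightConfig:
    """Sensor/flight geometry needed for the GSD.

    sensor_pixel_size : physical pixel pitch on the sensor, mm
    focal_length      : lens focal length, mm
    flight_altitude   : height above ground, m
    """

    sensor_pixel_size: float
    focal_length: float
    flight_altitude: float

    def __post_init__(self) -> None:
        if self.sensor_pixel_size <= 0:
            raise ParameterError("sensor_pixel_size must be > 0")
        if self.focal_length <= 0:
            raise ParameterError("focal_length must be > 0")
        if self.flight_altitude < 0:
            raise ParameterError("flight_altitude must be >= 0")


@dataclass
class IndexLayer:
    """A unitless per-pixel vegetation index with its validity mask."""

    values: np.ndarray
    index_kind: str  # "ExG" | "NDVI"
    nodata_mask: np.ndarray


def compute_gsd(config: FlightConfig) -> float:
    """Ground sample distance in m/pixel.

    GSD = sensor pixel size [mm] x flight altitude [m] / focal length [mm];
    the millimetres cancel, leaving metres on the ground per pixel.
    """
    return config.sensor_pixel_size * config.flight_altitude / config.focal_length


def gsd_cm(config: FlightConfig) -> float:
    """GSD rounded half-up to 2 decimals in centimetres (presentation)."""
    import decimal

    cm = decimal.Decimal(compute_gsd(config) * 100.0).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
    )
    return float(cm)


def excess_green(stack: SceneStack) -> IndexLayer:
    """ExG = 2g - r - b on chromatic coordinates g = G/(R+G+B) etc.

    Pixels where R+G+B = 0 carry no chromatic information and become nodata.
    """
    for name in ("R", "G", "B"):
        if name not in stack.bands:
            raise BandSchemaError(f"excess_green requires band {name!r}")
    r = stack.bands["R"].astype(np.float64)
    g = stack.bands["G"].astype(np.float64)
    b = stack.bands["B"].astype(np.float64)
    total = r + g + b
    nodata = stack.nodata_mask | (total == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = (2.0 * g - r - b) / total
    exg = np.where(nodata, np.nan, exg)
    return IndexLayer(values=exg, index_kind="ExG", nodata_mask=nodata)


def ndvi(stack: SceneStack) -> IndexLayer:
    """NDVI = (NIR - R) / (NIR + R); nodata where NIR + R = 0."""
    for name in ("R", "NIR"):
        if name not in stack.bands:
            raise BandSchemaError(f"ndvi requires band {name!r}")
    nir = stack.bands["NIR"].astype(np.float64)
    r = stack.bands["R"].astype(np.float64)
    total = nir + r
    nodata = stack.nodata_mask | (total == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (nir - r) / total
    out = np.where(nodata, np.nan, out)
    return IndexLayer(values=out, index_kind="NDVI", nodata_mask=nodata)


def vegetation_index(stack: SceneStack) -> IndexLayer:
    """The index matched to the sensor: ExG for RGB, NDVI when NIR exists."""
    if stack.sensor_kind == "multispectral":
        return ndvi(stack)
    return excess_green(stack)
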