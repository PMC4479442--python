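"""Minimal rectilinear georeferencing: map <-> pixel transforms.

Only north-up, axis-aligned transforms are supported (the common case for
orthomosaic products). Pixel (row, col) indexing has its origin at the
top-left pixel; coordinates are sampled at pixel centers.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np


class GridTransform(NamedTuple):
    """Affine map from pixel (col, row) to map (x, y).

    ``x = a * col + c`` and ``y = e * row + f`` evaluated at the pixel's
    upper-left corner; ``a > 0`` and ``e < 0`` for north-up rasters.
    Off-diagonal (rotation/shear) terms are not represented.
    """

    a: float  # pixel width (m), x-direction
    c: float  # x of the raster's upper-left corner
    e: float  # pixel height (m), negative for north-up
    f: float  # y of the raster's upper-left corner

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "GridTransform":
        """Transform for a raster whose top-left corner is (west, north)."""
        return cls(float(xsize), float(west), -float(ysize), float(north))

    def xy(self, row, col, offset: str = "center"):
        """Map coordinates of pixel (row, col); arrays broadcast."""
        shift = 0.5 if offset == "center" else 0.0
        x = self.a * (np.asarray(col) + shift) + self.c
        y = self.e * (np.asarray(row) + shift) + self.f
        return x, y

    def rowcol(self, x, y):
        """Fractional (row, col) of map coordinates (x, y)."""
        col = (np.asarray(x) - self.c) / self.a
        row = (np.asarray(y) - self.f) / self.e
        return row, col

    @property
    def pixel_size(self) -> tuple[float, float]:
        return abs(self.a), abs(self.e)

    def almost_equals(self, other: "GridTransform", tol_pixels: float = 0.5) -> bool:
        """True if both transforms agree within ``tol_pixels`` of this grid."""
        tol = tol_pixels * min(abs(self.a), abs(self.e))
        return (
            abs(self.a - other.a) < 1e-9 + 1e-6 * abs(self.a)
            and abs(self.e - other.e) < 1e-9 + 1e-6 * abs(self.e)
            and abs(self.c - other.c) <= tol
            and abs(self.f - other.f) <= tol
        )
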