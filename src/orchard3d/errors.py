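"""Exception hierarchy for the orchard3d pipeline.

Every error raised on purpose by the package derives from
:class:`Orchard3DError`, so callers (and the CLI) can catch one type.
"""


class Orchard3DError(Exception):
    """Base class for all orchard3d errors."""


class SceneAlignmentError(Orchard3DError):
    """Raster layers disagree in shape or georeferencing beyond half a pixel."""


class CrsUnitError(Orchard3DError):
    """The raster CRS is geographic (degrees); a planar metric CRS is required."""


class BandSchemaError(Orchard3DError):
    """A band required by the sensor kind or an operation is missing."""


class ParameterError(Orchard3DError):
    """Invalid segmentation or run parameters."""


class DegenerateDistributionError(Orchard3DError):
    """Automatic thresholding asked for on a single-valued distribution."""


class FeatureError(Orchard3DError):
    """A tree entity lacks the data needed to compute its geometric features."""


class PairingError(Orchard3DError):
    """Estimated/observed sequences cannot be paired (length mismatch)."""


class SingularFitError(Orchard3DError):
    """Regression requested on observations with zero variance."""


class ConfigError(Orchard3DError):
    """Invalid synthetic-scene or run configuration."""


class EmptySummaryError(Orchard3DError):
    """Field summary requested for an empty record list."""
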