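"""Exception hierarchy shared across the package."""


class BiomeShiftError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(BiomeShiftError):
    """Grid geometry is malformed (reversed latitudes, non-positive steps, ...)."""


class FormatError(BiomeShiftError):
    """A raster or table file does not satisfy the expected format contract."""


class UnknownCodeError(BiomeShiftError):
    """A grid carries a code that is absent from the attached scheme."""


class AlignmentError(BiomeShiftError):
    """Two rasters that must share geometry do not."""


class SpecError(BiomeShiftError):
    """A synthetic-data specification violates its invariants."""


class BiomeAbsentError(BiomeShiftError):
    """A per-biome statistic was requested for a biome not present in the grid."""


class DegenerateCentroidError(BiomeShiftError):
    """The 3-D mean vector of a biome's cells is numerically zero (antipodal balance)."""


class ConfigError(BiomeShiftError):
    """A run configuration file is invalid or references missing inputs."""
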