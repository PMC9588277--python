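"""Exception hierarchy.

The pipeline CLI maps these onto process exit codes: ConfigError -> 2,
DataError -> 3, AnalysisError -> 4.
"""


class PetIQError(Exception):
    """Base class for all package errors."""


class ConfigError(PetIQError):
    """Invalid or inconsistent run configuration."""


class DataError(PetIQError):
    """Problem with input data (files, volumes, metadata)."""


class VolumeError(DataError):
    """Invalid voxel volume (bad spacing, NaN voxels, mixed series...)."""


class GeometryError(DataError):
    """ROI or phantom geometry violates its constraints."""


class AnalysisError(PetIQError):
    """A metric computation cannot proceed (degenerate input, no crossing...)."""
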