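"""Exception hierarchy shared across the package.

Three broad classes map onto the CLI exit codes: input problems (bad files,
missing metadata) exit 2, degenerate data (empty selections, constant series)
exit 3, and configuration mistakes (impossible bands, unknown species) exit 4.
"""


class BsdetectError(Exception):
    """Base class for all package-specific errors."""


class InputError(BsdetectError):
    """A problem with an input file or its metadata."""


class DimensionalityError(InputError):
    """An image does not have the expected number of dimensions."""


class MetadataError(InputError):
    """Required metadata (e.g. repetition time) is missing or invalid."""


class ConfigError(BsdetectError):
    """A configuration value is out of its valid range."""


class BandError(ConfigError):
    """A frequency band is empty or exceeds the Nyquist limit."""


class DegenerateDataError(BsdetectError):
    """The data admit no meaningful result (empty selection, zero variance...)."""


class EmptySelectionError(DegenerateDataError):
    """A voxel-selection step removed every voxel."""


class ConstantSeriesError(DegenerateDataError):
    """A time series is constant where variance is required."""


class SamplingError(DegenerateDataError):
    """The sampling rate cannot resolve the requested frequency band."""
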