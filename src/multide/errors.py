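"""Exception hierarchy.

All data-dependent failures derive from :class:`MultiDEError` so callers (and
the CLI, which maps them to exit code 3) can distinguish validation problems
from programming errors.
"""


class MultiDEError(Exception):
    """Base class for all multide data/validation errors."""


class FormatError(MultiDEError):
    """Counts file is malformed (non-integer or negative entries, bad header)."""


class MetadataError(MultiDEError):
    """Sample metadata does not cover the counts file or is malformed."""


class DesignError(MultiDEError):
    """Study design is invalid, e.g. an incomplete subject x condition grid."""


class EmptyResultError(MultiDEError):
    """An operation (e.g. gene filtering) produced an empty result."""


class DegenerateSampleError(MultiDEError):
    """A sample has a zero summary statistic (median/total/quartile)."""


class InsufficientGenesError(MultiDEError):
    """Too few usable genes remain, e.g. after TMM trimming."""


class UndefinedDispersionError(MultiDEError):
    """Dispersion cannot be estimated (gene with zero mean in every condition)."""


class ZeroMeanError(MultiDEError):
    """A (gene, condition) cell has zero sample mean; log-mean is undefined."""


class DegenerateInteractionError(MultiDEError):
    """Interaction matrix is identically zero; rank-1 factors are undefined."""


class UnstableReferenceError(MultiDEError):
    """The reference condition's interaction factor is numerically zero."""


class ConfigError(MultiDEError):
    """Invalid simulation or run configuration."""
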