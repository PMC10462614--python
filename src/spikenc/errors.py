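"""Exception hierarchy for spikenc.

All spikenc-specific failures derive from :class:`SpikencError` so callers can
catch the package's errors with a single clause while still distinguishing the
usual Python categories (``ValueError``, ``RuntimeError``).
"""


class SpikencError(Exception):
    """Base class for all spikenc errors."""


class ConfigurationError(SpikencError, ValueError):
    """A parameter or preset is invalid or unknown."""


class DataError(SpikencError, ValueError):
    """Input data violate a precondition (non-finite values, too few trials...)."""


class DimensionError(SpikencError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class FormatError(SpikencError, ValueError):
    """An input file or raster has an unsupported layout."""


class IntegrityError(SpikencError, RuntimeError):
    """A serialized model file is missing required content or is corrupted."""


class NumericError(SpikencError, ArithmeticError):
    """A numerical operation failed (e.g. a singular noise covariance)."""


class NotFittedError(SpikencError, RuntimeError):
    """An operation requires a fitted model."""
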