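"""Exception hierarchy for the issoselect pipeline.

Every stage raises a subclass of :class:`IssoSelectError` so callers can
catch pipeline failures without masking programming errors.
"""


class IssoSelectError(Exception):
    """Base class for all issoselect errors."""


class ParseError(IssoSelectError):
    """Malformed input file (ragged rows, unreadable cells)."""


class SchemaError(IssoSelectError):
    """Input table violates the declared schema (e.g. non-binary target)."""


class ConfigError(IssoSelectError):
    """Unknown configuration key."""


class ValidationError(IssoSelectError):
    """Configuration value outside its allowed range."""


class ImputeError(IssoSelectError):
    """Imputation impossible (e.g. a column entirely missing)."""


class DegenerateColumnError(IssoSelectError):
    """A column with zero spread where spread is required."""


class SmoteError(IssoSelectError):
    """Minority class too small to interpolate."""


class StratificationError(IssoSelectError):
    """A class has fewer samples than the requested number of folds."""


class StateError(IssoSelectError):
    """Operation called before its preconditions were established."""


class SpecError(IssoSelectError):
    """Invalid synthetic-data specification."""


class KernelWidthError(IssoSelectError):
    """All surrogate sample weights collapsed to zero."""
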