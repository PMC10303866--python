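"""Exception hierarchy for the vermicelli pipeline.

Every error raised on a contract violation derives from
:class:`VermicelliError` so callers can catch pipeline failures
without masking programming errors.
"""


class VermicelliError(Exception):
    """Base class for all pipeline errors."""


class ParseError(VermicelliError):
    """A file could not be parsed; message names the offending line."""


class BoundsError(VermicelliError):
    """An index referenced a bin outside the declared bin table."""


class SchemaError(VermicelliError):
    """A tabular input is missing required columns."""


class ValidationError(VermicelliError):
    """Input data violates a documented invariant (e.g. negative intensity)."""


class DimensionError(VermicelliError):
    """Array/bin-table shapes do not agree."""


class ParameterError(VermicelliError):
    """A parameter value is outside its documented domain."""


class InsufficientDataError(VermicelliError):
    """Too few observations for the requested estimator."""


class DegenerateInputError(VermicelliError):
    """Input is structurally degenerate (empty mask, zero total, ...)."""


class AlignmentError(VermicelliError):
    """Two inputs that must share a grid (bins, time points) do not."""


class ConfigError(VermicelliError):
    """Unknown or ill-typed configuration key."""


class UsageError(VermicelliError):
    """Unknown pipeline stage or CLI misuse."""
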