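"""Exception hierarchy for the stunflow pipeline."""


class StunflowError(Exception):
    """Base class for all package errors."""


class ParameterError(StunflowError, ValueError):
    """An operation was called with an out-of-range parameter."""


class ConfigurationError(StunflowError, ValueError):
    """A scenario / run configuration is internally inconsistent."""


class FormatError(StunflowError, ValueError):
    """An input array or file does not have the expected shape or type."""


class ContractViolation(StunflowError, RuntimeError):
    """A pluggable provider returned output violating its contract."""


class EmptyMaskError(StunflowError, RuntimeError):
    """A frame had no foreground pixels where activity was requested."""


class AnalysisError(StunflowError, RuntimeError):
    """A summary statistic was requested on an empty or invalid window."""


class DataError(StunflowError, ValueError):
    """A data vector violates its invariants (empty sample, p outside [0,1], ...)."""


class SchemaError(StunflowError, ValueError):
    """A CSV file does not match its declared schema."""
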