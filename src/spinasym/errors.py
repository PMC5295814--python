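"""Exception hierarchy for table validation and pipeline failures."""


class SpinasymError(Exception):
    """Base class for all package errors."""


class SchemaError(SpinasymError):
    """A required column is missing or the header is malformed."""


class RowValueError(SpinasymError):
    """A cell violates a value invariant; the message names the offending row."""


class PairingError(SpinasymError):
    """A sample is missing one of its two sides."""


class UniquenessError(SpinasymError):
    """Duplicate rows under the table's uniqueness key."""


class CoordinateError(SpinasymError):
    """An interval is empty or inverted after coordinate normalization."""


class ConfigError(SpinasymError):
    """A configuration value is outside its documented domain."""


class StageError(SpinasymError):
    """An unknown developmental-stage label."""


class PipelineError(SpinasymError):
    """A pipeline stage failed; the message is tagged with the stage name."""
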