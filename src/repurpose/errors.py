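"""Exception hierarchy shared across the pipeline."""


class RepurposeError(Exception):
    """Base class for all package errors."""


class TableFormatError(RepurposeError):
    """A file does not conform to the declared tabular schema."""


class TableValidationError(RepurposeError):
    """A record violates a domain invariant (bad enum, out-of-range value...)."""


class ConfigError(RepurposeError):
    """An invalid configuration value (threshold, mix, size...)."""


class AnalysisError(RepurposeError):
    """An analysis precondition is not met (empty universe, tiny bins...)."""
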