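"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError):
    """Invalid simulation or analysis configuration (user error)."""


class SchemaError(PipelineError):
    """A delimited-text input does not match the expected schema."""


class DataValidationError(PipelineError):
    """Well-formed input with invalid content (labels, domains, duplicates)."""


class AnalysisError(PipelineError):
    """A statistical step cannot proceed (degenerate or insufficient data)."""
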