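"""Exception types shared across the pipeline."""


class ImmunexpoError(Exception):
    """Base class for package-specific errors."""


class ConfigError(ImmunexpoError):
    """Invalid configuration; message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class AlignmentError(ImmunexpoError):
    """Sample indexes of two tables do not line up."""


class DegenerateDataError(ImmunexpoError):
    """Input data is degenerate for the requested operation
    (constant vector, undefined skewness, all-missing feature, ...)."""
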