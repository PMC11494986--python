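"""Exception hierarchy shared across the package."""


class FlocProfilerError(Exception):
    """Base class for all package errors."""


class SchemaError(FlocProfilerError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(FlocProfilerError):
    """A record violates a documented bound or invariant."""


class DuplicateKeyError(ValidationError):
    """A key that must be unique appears more than once."""

    def __init__(self, message: str, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []


class TaxonomyParseError(FlocProfilerError):
    """A GTDB-style taxonomy string could not be parsed."""


class ConfigError(FlocProfilerError):
    """A run or simulation configuration is invalid or infeasible."""
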