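"""Exception hierarchy shared across the pipeline stages."""


class SdegkitError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(SdegkitError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(SdegkitError):
    """An input table, list, or matrix violates a stage precondition."""


class SchemaError(InputError):
    """A tabular input is missing mandatory columns or has duplicate keys."""


class ParseError(InputError):
    """A text input (e.g. GMT) is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NormalizationError(SdegkitError):
    """Median-ratio normalization cannot proceed (no all-positive reference gene)."""


class ThresholdError(SdegkitError):
    """A sign side has too few distinct SS values to derive a cluster threshold."""


class DegenerateInputError(SdegkitError):
    """Fewer than two distinct values supplied to the 1-D clusterer."""
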