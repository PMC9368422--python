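"""Exception hierarchy for the affectgait pipeline.

The CLI maps these onto distinct exit codes (usage 2, parse 3, validation 4),
so every stage raises the most specific class that applies.
"""


class AffectGaitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AffectGaitError):
    """A configuration object is internally inconsistent or unusable."""


class MappingNotInvertibleError(ConfigurationError):
    """The metric-to-PAD matrix cannot be inverted on the requested targets."""


class InputError(AffectGaitError):
    """Invalid input data (base for parse and validation errors)."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:" + (f"{line}: " if line is not None else " ")
        super().__init__(prefix + message)


class ValidationError(InputError):
    """Parsed data violates a domain constraint (range, ordering, identity)."""


class UsageError(AffectGaitError):
    """The operation was called in a way that makes no sense (wrong dimension,
    missing report, empty matrix, ...)."""


class EmptyMatrixError(UsageError):
    """A classification report was requested for a confusion matrix with no mass."""
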