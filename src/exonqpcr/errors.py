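"""Exception hierarchy for the qPCR pipeline.

Every error raised by this package derives from :class:`QpcrError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class QpcrError(Exception):
    """Base class for all errors raised by exonqpcr."""


class FormatError(QpcrError):
    """A file does not have the expected structure (e.g. missing column)."""


class ParseError(QpcrError):
    """A field value could not be parsed; carries the 1-based file line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(QpcrError):
    """Parsed data violates an invariant (duplicate keys, bad manifest...)."""


class DataError(QpcrError):
    """The data set is structurally incomplete for the requested analysis
    (e.g. a missing housekeeper group or reference-dose group)."""


class UsageError(QpcrError):
    """A function was called with arguments that never make sense."""
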