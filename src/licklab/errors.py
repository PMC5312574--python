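"""Exception hierarchy shared across the package."""


class LickLabError(Exception):
    """Base class for all licklab errors."""


class ValidationError(LickLabError):
    """A domain object violates one of its invariants."""


class OrderingError(ValidationError):
    """Event times are not non-decreasing."""


class ProtocolError(LickLabError):
    """A session stream violates the session protocol (e.g. no leading RFID scan)."""


class ParseError(LickLabError):
    """A CSV log could not be parsed; the message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AlignmentError(LickLabError):
    """Two time series share no overlapping samples."""


class DomainError(ValueError, LickLabError):
    """An argument is outside an operation's domain."""
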