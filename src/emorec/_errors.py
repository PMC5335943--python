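"""Exception hierarchy shared across the package."""


class EmorecError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EmorecError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSignalError(EmorecError, ValueError):
    """A signal has zero variance, so slope descriptors are undefined."""


class ParseError(EmorecError, ValueError):
    """A recording or profile file is malformed.

    Carries the 1-based line number when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PersistenceError(EmorecError, ValueError):
    """A stored model or profile cannot be loaded (bad version/schema)."""
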