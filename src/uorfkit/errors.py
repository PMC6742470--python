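"""Exception hierarchy.

``UsageError`` maps to exit code 1 (configuration / invocation problems),
``DataError`` to exit code 2 (malformed or inconsistent input data).
"""


class UorfkitError(Exception):
    """Base class for all package errors."""


class UsageError(UorfkitError):
    """Bad configuration or invocation."""


class DataError(UorfkitError):
    """Malformed or internally inconsistent input data."""


class GtfParseError(DataError):
    """Unparseable GTF record; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
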