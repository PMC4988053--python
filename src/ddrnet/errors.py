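"""Exception types shared across the package.

All data-level failures derive from :class:`DataError` so callers (and the
CLI) can distinguish malformed input (exit code 2) from usage errors
(exit code 1).
"""


class DataError(ValueError):
    """Base class for malformed or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class FormatError(DataError):
    """A file is structurally not in the expected dialect (e.g. missing columns)."""


class GenerationError(RuntimeError):
    """Synthetic-scenario geometry is infeasible for the requested parameters."""
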