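"""Exception types shared across the pipeline."""


class EpiloopError(Exception):
    """Base class for all package errors."""


class ParseError(EpiloopError):
    """A file could not be parsed; carries the file and (1-based) line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(EpiloopError):
    """Input values violate a documented invariant."""


class IntegrityError(EpiloopError):
    """Pipeline artifacts are inconsistent with each other (e.g. a pair refers
    to a segment missing from the feature table)."""
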