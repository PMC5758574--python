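"""Typed exceptions raised by the twindiff pipeline."""


class TwindiffError(Exception):
    """Base class for all package errors."""


class FormatError(TwindiffError):
    """A malformed input file (bad header, bad field, bad value).

    Carries the offending file and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DesignError(TwindiffError):
    """An invalid twin-pair design (duplicate pair, two affected members, no pairs...)."""


class ConfigError(TwindiffError):
    """An invalid simulation or pipeline configuration."""


class AnalysisError(TwindiffError):
    """A statistical operation called on inputs that violate its preconditions."""
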