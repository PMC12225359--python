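"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition (non-positive interval,
    malformed band, too few peaks, ...)."""


class RRFileParseError(ValueError):
    """A text file could not be parsed; carries the offending line number."""

    def __init__(self, path, line_number: int, line: str, reason: str = ""):
        self.path = str(path)
        self.line_number = line_number
        self.line = line
        msg = f"{self.path}: cannot parse line {line_number}: {line!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class EmptySeriesWarning(UserWarning):
    """An operation received or produced an empty series; the result is a
    valid empty object."""


class UnitWarning(UserWarning):
    """Values look implausible for the declared unit (milliseconds)."""
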