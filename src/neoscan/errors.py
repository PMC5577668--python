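"""Exception hierarchy for neoscan."""


class NeoscanError(Exception):
    """Base class for all neoscan errors."""


class ValidationError(NeoscanError):
    """A domain object violates one of its invariants."""


class ParseError(NeoscanError):
    """An input file could not be parsed; carries file context."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class FormatError(NeoscanError):
    """An input file is structurally unusable (e.g. a required column is absent)."""


class InfeasiblePlantError(NeoscanError):
    """A requested planted-binder configuration cannot be realised by the matrix scorer."""
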