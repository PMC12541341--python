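"""Exception types shared across the package."""

from __future__ import annotations


class CalcipairError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CalcipairError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedGeometryError(CalcipairError):
    """Raised for non-orthorhombic simulation cells."""


class ContractError(CalcipairError):
    """An operation was called on an object in an illegal state
    (e.g. association free energy from an unaligned PMF)."""
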