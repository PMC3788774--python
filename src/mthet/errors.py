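"""Exception hierarchy for the mthet package."""


class MthetError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MthetError, ValueError):
    """A position falls outside the genome or an unmapped coordinate was requested."""


class ValidationError(MthetError, ValueError):
    """Invalid input values (bad bases, rates outside [0,1], malformed specs...)."""


class ReferenceMismatchError(MthetError, ValueError):
    """Neither observed allele matches the reference base at the position."""


class SignalError(MthetError, ValueError):
    """Degenerate electropherogram signal (e.g. zero total peak height)."""


class InsufficientReadsError(MthetError, ValueError):
    """Fewer sequence reads than required to estimate a heteroplasmy level."""


class ParseError(MthetError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
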