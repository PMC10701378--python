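"""Exception taxonomy shared across the package."""


class HotwalkError(Exception):
    """Base class for all package errors."""


class ValidationError(HotwalkError, ValueError):
    """Input violates a documented invariant (bad group label, bad params...)."""


class FormatError(ValidationError):
    """A file does not conform to the expected schema/dialect."""


class DegenerateDataError(ValidationError):
    """A statistical routine received data it cannot operate on
    (constant sample, zero margin, too few observations)."""


class NumericError(HotwalkError, ArithmeticError):
    """A numerical computation blew up (non-finite covariance etc.)."""
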