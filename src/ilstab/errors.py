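"""Exception hierarchy shared across the package."""


class IlstabError(Exception):
    """Base class for all package errors."""


class FormatError(IlstabError):
    """A delimited table could not be parsed; carries the offending line."""


class IntegrityError(IlstabError):
    """Parsed data violates a structural invariant (duplicates, gaps)."""


class PreconditionError(IlstabError, ValueError):
    """An operation was called with inputs outside its contract."""


class FittingError(IlstabError):
    """A nonlinear fit failed to converge; carries diagnostics."""


class DegenerateNormalizationError(PreconditionError):
    """Normalization anchors coincide (y0 == ymax)."""


class InsufficientWindowError(PreconditionError):
    """Too few points inside the |dG| transition window for a linear fit."""
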