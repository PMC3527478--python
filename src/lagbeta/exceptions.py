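"""Exception hierarchy for lagbeta.

All errors raised on bad user input derive from :class:`LagbetaError` so a
caller (or the CLI) can catch one type.
"""


class LagbetaError(ValueError):
    """Base class for all lagbeta input/validation errors."""


class FormatError(LagbetaError):
    """Malformed input table: missing columns, duplicate ids, unparseable cells."""


class ValidationError(LagbetaError):
    """Well-formed input with invalid values (negative intensity, bad vocabulary)."""


class AlignmentError(LagbetaError):
    """Fingerprint, metadata and chemistry tables share no usable sample keys."""


class InsufficientDataError(LagbetaError):
    """Too few observations for the requested statistic (e.g. < 3 lag pairs)."""


class DegenerateDesignError(LagbetaError):
    """A design matrix has a constant column or zero variance in the predictor."""


class SaturatedDesignError(LagbetaError):
    """The constrained design leaves no residual degrees of freedom."""
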