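"""Exception hierarchy for bgblup."""


class BgblupError(Exception):
    """Base class for all bgblup errors."""


class ParameterError(BgblupError, ValueError):
    """An argument is outside its admissible range."""


class EstimabilityError(BgblupError):
    """A fixed-effects (least-squares) system is rank deficient.

    Raised when n < p or X'X is singular, i.e. the classic situation in
    which ordinary least squares cannot separate marker effects and a
    shrinkage estimator is required.
    """


class AlignmentError(BgblupError, ValueError):
    """Labels or dimensions of two objects do not line up."""


class FormatError(BgblupError, ValueError):
    """A data file violates the expected tabular layout."""


class SolverError(BgblupError):
    """A linear system arising in (G + lambda*D) could not be solved."""
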