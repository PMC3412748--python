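"""Exception hierarchy for the scoring and analysis pipeline.

Validation problems (bad inputs, malformed sessions or files) derive from
:class:`ValidationError`; numerical failures (degenerate fits, separation,
singular covariances) derive from :class:`NumericalError`.  The CLI maps the
two branches to exit codes 2 and 3 respectively.
"""


class PtssRiskError(Exception):
    """Base class for all package errors."""


class ValidationError(PtssRiskError, ValueError):
    """Invalid input data, configuration or file contents."""


class NumericalError(PtssRiskError, ArithmeticError):
    """A computation failed for numerical/statistical reasons."""


class InvalidInputError(ValidationError):
    pass


class EmptyWindowError(ValidationError):
    """A scoring window contains no samples (or no terminating beat)."""


class SessionShapeError(ValidationError):
    """A session does not have the trial/phase structure the paradigm requires."""


class ParseError(ValidationError):
    """An epoch TSV or sidecar could not be parsed; message names line/field."""


class DegenerateFitError(NumericalError):
    """Too few usable points, or a degenerate distribution, for a fit."""


class DegenerateCalibrationError(NumericalError):
    """Singular pooled covariance in discriminant calibration."""


class SeparationError(NumericalError):
    """Complete or quasi-complete separation in a logistic fit."""


class CollinearityError(NumericalError):
    """Design matrix is rank deficient (e.g., duplicated covariate)."""


class ConvergenceError(NumericalError):
    """An iterative fit failed to converge."""
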