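"""Exception hierarchy shared across the pipeline stages."""


class BBBFluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BBBFluxError, ValueError):
    """A physical quantity violates its domain (e.g. non-positive time or area)."""


class UndefinedEffluxError(BBBFluxError, ZeroDivisionError):
    """Efflux ratio requested with zero A-to-B permeability."""


class InsufficientDataError(BBBFluxError, ValueError):
    """Too few usable observations for the requested estimate."""


class FitFailureError(BBBFluxError, RuntimeError):
    """Nonlinear fit failed to converge from every start."""


class DegenerateRegressionError(BBBFluxError, ValueError):
    """Regression requested on a zero-variance predictor."""


class SchemaError(BBBFluxError, ValueError):
    """Tabular input does not match the documented column schema."""
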