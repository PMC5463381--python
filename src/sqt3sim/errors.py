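"""Exception hierarchy shared across the package."""


class Sqt3SimError(Exception):
    """Base class for package errors."""


class DomainError(Sqt3SimError, ValueError):
    """An argument lies outside its physical domain."""


class IntegrityError(Sqt3SimError, ValueError):
    """A state or field contains NaN/inf or violates an invariant."""


class InstabilityError(Sqt3SimError, RuntimeError):
    """Numerical divergence of the explicit integrator."""

    def __init__(self, message, t_ms=None, node=None):
        super().__init__(message)
        self.t_ms = t_ms
        self.node = node


class MeasurementError(Sqt3SimError, RuntimeError):
    """A biomarker could not be extracted from a trace."""


class ProtocolError(Sqt3SimError, RuntimeError):
    """A stimulation protocol produced no classifiable outcome."""


class CalibrationError(Sqt3SimError, RuntimeError):
    """Variant calibration or curve fitting failed to converge."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class MappingError(Sqt3SimError, KeyError):
    """A drug-block entry does not map onto a model conductance."""


class UnsupportedDoseError(Sqt3SimError, ValueError):
    """Verbatim block tables exist only at the tabulated doses."""


class ConfigError(Sqt3SimError, ValueError):
    """Invalid run configuration."""


class AlignmentError(Sqt3SimError, ValueError):
    """Two traces do not share a sampling grid / stimulus alignment."""
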