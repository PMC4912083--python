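"""Exception hierarchy for il1p38."""


class Il1P38Error(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(Il1P38Error, ValueError):
    """A numeric argument violates a precondition (negative rate, bad dose...)."""


class SpecificationError(Il1P38Error, ValueError):
    """A ModelSpec is internally inconsistent (unknown species, bad group...)."""


class ConfigurationError(Il1P38Error, ValueError):
    """A scenario/parameter configuration cannot be applied to the model."""


class SolverError(Il1P38Error, RuntimeError):
    """Numerical integration failed.

    Carries ``last_time``, the last time point the integrator reached.
    """

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class ConvergenceError(Il1P38Error, RuntimeError):
    """A steady-state search did not reach the requested residual.

    Carries ``residual``, the best max-norm of d/dt achieved (nM/s).
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CalibrationError(Il1P38Error, RuntimeError):
    """Parameter calibration found no feasible set within the budget.

    Carries ``report``, per-constraint diagnostics of the best candidate.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report
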