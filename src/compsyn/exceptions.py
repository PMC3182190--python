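"""Exception hierarchy for compsyn."""


class CompsynError(Exception):
    """Base class for all compsyn errors."""


class InvalidParameterError(CompsynError, ValueError):
    """Activation probabilities outside the open unit interval."""


class DegenerateParametersError(CompsynError):
    """Dynamics has no usable interior fixed point or a degenerate protocol."""


class MarginalStabilityError(CompsynError):
    """|drift'(x*)| too small to define a finite relaxation time."""


class IntegrationInstabilityError(CompsynError):
    """The integrator stepped outside [0, 1]; reduce dt."""


class InadmissibleSignalError(CompsynError, ValueError):
    """A signal would push an activation probability outside (0, 1)."""


class ZeroShiftError(CompsynError, ValueError):
    """A protocol phase with zero parameter shift; learning time undefined."""


class NonConvergenceError(CompsynError):
    """Saturation (or a required level crossing) not reached within max_time."""


class EstimationError(CompsynError):
    """Not enough data for a requested statistical estimate."""


class ConfigurationError(CompsynError, ValueError):
    """Invalid run configuration."""
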