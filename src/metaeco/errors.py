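"""Exception hierarchy shared across the package."""


class MetaecoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MetaecoError, ValueError):
    """A parameter is outside its admissible range."""


class TopologyError(MetaecoError, ValueError):
    """The requested spatial topology is infeasible (e.g. ring with n < 3)."""


class AssemblyError(MetaecoError, ValueError):
    """Matrix components are not conformable."""


class NumericalError(MetaecoError, ArithmeticError):
    """A numerical routine received or produced non-finite values."""


class UnsupportedPredictionError(MetaecoError, NotImplementedError):
    """No closed-form spectral prediction exists for this configuration."""


class SolverError(MetaecoError, RuntimeError):
    """An equilibrium solve failed (singular system or non-convergence)."""


class FeasibilitySamplingError(MetaecoError, RuntimeError):
    """Rejection sampling for feasible systems exhausted its attempt budget."""


class ConfigError(MetaecoError, ValueError):
    """A configuration document failed schema validation."""
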