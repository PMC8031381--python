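"""Exception hierarchy for rowerchain."""


class RowerChainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RowerChainError, ValueError):
    """Invalid chain specification or manifest."""


class NumericalError(RowerChainError, RuntimeError):
    """A numerical operation failed (e.g. mobility not positive definite)."""


class IntegrationError(RowerChainError, RuntimeError):
    """The integrator left the valid state space; reduce the time step."""


class AssumptionViolationError(RowerChainError, ValueError):
    """Observed data violate a modelling assumption (e.g. count > n_sites)."""
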