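"""Exception types shared across the package."""


class NeuritesimError(Exception):
    """Base class for package errors."""


class DomainError(NeuritesimError, ValueError):
    """A parameter or evaluation point lies outside its permitted domain."""


class InfeasibleSpecError(NeuritesimError, ValueError):
    """A steady-state specification admits no consistent parameter set.

    The message names the violated relation.
    """


class SchemaError(NeuritesimError, ValueError):
    """A configuration file or trajectory violates its schema."""


class IntegrationError(NeuritesimError, RuntimeError):
    """The ODE integrator failed; the message names the offending component."""
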