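"""Exception hierarchy shared across the package."""


class VoltfluxError(Exception):
    """Base class for all package-specific errors."""


class ModelParseError(VoltfluxError):
    """A model document (SBML or native text) could not be parsed."""


class ModelValidationError(VoltfluxError):
    """A structurally invalid model: dangling ids, bad bounds, empty parts."""


class UnknownIdError(ModelValidationError, KeyError):
    """A reaction or metabolite id that is not declared in the model."""


class SolverError(VoltfluxError):
    """The LP backend failed for a reason other than infeasible/unbounded."""


class InfeasibleProblemError(SolverError):
    """The LP constraint set admits no solution."""


class UnboundedProblemError(SolverError):
    """The LP objective is unbounded — typically an open loop bound."""


class ConfigurationError(VoltfluxError):
    """A mode configuration references species missing from the model."""
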