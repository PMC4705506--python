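"""Exception hierarchy shared across the engine."""


class CohortCEAError(Exception):
    """Base class for all engine errors."""


# Deliberately not a ValueError: pydantic would swallow it inside validators
# and re-raise a wrapped ValidationError, hiding the engine's error type.
class ModelValidationError(CohortCEAError):
    """An input violates a model-level constraint (domain, bounds, references)."""


class ResidualError(ModelValidationError):
    """Competing exits from a state exceed 1, leaving a negative self-transition."""

    def __init__(self, state_id: str, cycle_index: int, residual: float):
        self.state_id = state_id
        self.cycle_index = cycle_index
        self.residual = residual
        super().__init__(
            f"exits from state '{state_id}' at cycle {cycle_index} exceed 1 "
            f"(residual self-transition {residual:.6g}); reduce the competing "
            f"transition probabilities or shorten the cycle"
        )


class LifeTableError(CohortCEAError, ValueError):
    """Life-table lookup failed or the table violates its invariants."""


class MappingRangeError(CohortCEAError, ValueError):
    """A score lies outside the declared input range of a mapping algorithm."""


class PathError(CohortCEAError, KeyError):
    """A parameter path does not resolve against the model specification."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


class DistributionError(CohortCEAError, ValueError):
    """Infeasible distribution parameterisation (e.g. beta variance too large)."""


class PSAError(CohortCEAError, RuntimeError):
    """Probabilistic sensitivity analysis aborted (e.g. rejection cap exceeded)."""


class ParameterSetError(CohortCEAError, ValueError):
    """A parameter set failed validation; carries the full report."""

    def __init__(self, report):
        self.report = report
        super().__init__(report.render())
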