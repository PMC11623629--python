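"""Exception hierarchy for the repgeom pipeline.

All argument/contract violations derive from :class:`RepgeomError` so callers
can catch pipeline failures without masking programming errors.
"""


class RepgeomError(Exception):
    """Base class for all repgeom-specific errors."""


class InvalidArgumentError(RepgeomError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidInputError(RepgeomError, ValueError):
    """Input data (labels, shapes, file contents) violate a schema."""


class GenerationError(RepgeomError, RuntimeError):
    """A stochastic generator exhausted its retry budget."""


class UndefinedCorrelationError(RepgeomError, ValueError):
    """A correlation is undefined (zero-variance input)."""


class UndefinedDistanceError(RepgeomError, ValueError):
    """A distance is undefined (e.g. zero-norm vector under cosine)."""


class IncompleteCoverageError(RepgeomError, ValueError):
    """Aggregation input does not cover every stimulus pair."""


class RankDeficiencyError(RepgeomError, ValueError):
    """Design/predictor matrix is rank deficient."""

    def __init__(self, msg, dependent=()):
        super().__init__(msg)
        self.dependent = tuple(dependent)


class NumericalError(RepgeomError, ArithmeticError):
    """A numerical operation failed (singular matrix, overflow)."""


class TrialExcludedError(RepgeomError, ValueError):
    """A gaze trial has no valid samples and must be excluded."""


class EmptyCohortError(RepgeomError, ValueError):
    """Every participant was screened out."""


class SchemaError(InvalidInputError):
    """A file does not match its declared schema."""
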