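"""Exception hierarchy for the bargaining-table package."""


class BargainingTableError(Exception):
    """Base class for all package-specific errors."""


class AssignmentShapeError(BargainingTableError):
    """An assignment vector does not match the board's disc list."""


class FocalTieError(BargainingTableError):
    """A disc is equidistant from both player squares, so the closeness
    rule (and everything built on it) is undefined for the board."""


class DegeneratePositionError(BargainingTableError):
    """A disc coincides with a player square (zero distance)."""


class EmptyBoardError(BargainingTableError):
    """An operation that needs at least one disc got an empty board."""


class NoDataError(BargainingTableError):
    """Model fitting or evaluation received an empty dataset."""


class FeatureSchemaError(BargainingTableError):
    """Features offered at prediction time do not match the manifest the
    model was trained with (e.g. an SVO-less model given an SVO column)."""


class ConfigError(BargainingTableError):
    """Invalid or empty configuration (e.g. an empty hyperparameter grid)."""


class ConstraintInfeasibleError(BargainingTableError):
    """The evaluation-set search exhausted its budget.

    Carries ``best_residual``, the smallest absolute deviation from the
    target focal total seen before giving up.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class SessionShapeError(BargainingTableError):
    """Boards and recorded opponent assignments differ in length."""


class PopulationError(BargainingTableError):
    """A tournament population is missing one of the two sides."""


class SummaryError(BargainingTableError):
    """Summary statistics requested for an empty collection."""
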