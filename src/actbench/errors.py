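"""Exception hierarchy for actbench."""


class ActBenchError(Exception):
    """Base class for all actbench errors."""


class SchemaError(ActBenchError):
    """An input file is missing required columns or has a malformed header."""


class ValidationError(ActBenchError):
    """Rows violate the documented category domains or type constraints.

    ``rows`` holds the offending file row numbers (header = row 1).
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ReferentialIntegrityError(ActBenchError):
    """A patient references a hospital_id absent from the hospital table."""


class ConfigurationError(ActBenchError):
    """A generator or pipeline configuration is infeasible or inconsistent."""


class SeparationError(ActBenchError):
    """A covariate level perfectly predicts the outcome (complete separation)."""

    def __init__(self, message: str, covariate: str | None = None):
        super().__init__(message)
        self.covariate = covariate


class ModelError(ActBenchError):
    """Model fitting failed (singular design, non-convergence, degenerate input)."""


class UndefinedStatisticError(ActBenchError):
    """A statistic is undefined for the given input (e.g. CV at mean rate 0)."""
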