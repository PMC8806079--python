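"""Exception hierarchy for the thirdvar package."""


class ThirdvarError(Exception):
    """Base class for all package errors."""


class CohortFormatError(ThirdvarError):
    """Input file violates the documented cohort CSV dialect."""


class EmptyInputError(ThirdvarError):
    """Input file or table contains no data rows."""


class CohortParseError(ThirdvarError):
    """One or more cells failed type coercion.

    Carries ``issues``: a list of ``(row_index, column, raw_value)`` tuples so
    no failing row is silently dropped.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        preview = "; ".join(
            f"row {r} col {c!r}: {v!r}" for r, c, v in self.issues[:5]
        )
        more = "" if len(self.issues) <= 5 else f" (+{len(self.issues) - 5} more)"
        super().__init__(f"{len(self.issues)} cell(s) failed coercion: {preview}{more}")


class CodingError(ThirdvarError):
    """A categorical value outside the enumerated levels."""


class DomainError(ThirdvarError):
    """A numeric argument outside the mathematical domain of an operation."""


class DegenerateScaleError(ThirdvarError):
    """A column with zero standard deviation where scaling is required."""


class CollinearityError(ThirdvarError):
    """Rank-deficient design matrix.

    ``column`` names the first column linearly dependent on its predecessors.
    """

    def __init__(self, column, message=None):
        self.column = column
        super().__init__(message or f"design matrix is rank deficient at column {column!r}")


class EmptyAnalysisError(ThirdvarError):
    """No rows survive complete-case filtering."""


class DegenerateTableError(ThirdvarError):
    """Contingency table with a zero marginal total."""


class ContractError(ThirdvarError):
    """An internal API contract was violated by the caller."""


class ConfigError(ThirdvarError):
    """Invalid run configuration or generator parameters."""


class InsufficientGroupError(ThirdvarError):
    """A subgroup is below the minimum size for stratified analysis."""


class UndefinedStatisticError(ThirdvarError):
    """A test statistic is undefined for the given inputs (0/0)."""
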