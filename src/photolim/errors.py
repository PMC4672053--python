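"""Exception hierarchy for gas-exchange analysis failures.

Every error raised by the package derives from :class:`PhotolimError`,
so callers can catch analysis failures without masking programming bugs.
"""


class PhotolimError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PhotolimError, ValueError):
    """An input violates the mathematical domain of a formula."""


class SchemaError(PhotolimError):
    """A required column cannot be resolved in an input table."""


class EmptyInputError(PhotolimError):
    """An input file or table contains no usable rows."""


class ShapeError(PhotolimError):
    """Columns of a result table have inconsistent lengths."""


class ConvergenceError(PhotolimError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnderdeterminedError(PhotolimError):
    """Too few informative points to identify a model parameter."""

    def __init__(self, message: str, parameter: str | None = None):
        super().__init__(message)
        self.parameter = parameter


class SingularityError(DomainError):
    """Electron transport is inconsistent with gross assimilation
    (denominator of the variable-J inversion vanishes)."""


class InvalidPointError(PhotolimError):
    """A per-point estimate is physically inadmissible and is flagged."""


class EmptyWindowError(PhotolimError):
    """No valid point falls inside the averaging window."""


class IllConditionedError(PhotolimError):
    """A linear system is too close to singular to solve reliably."""


class PairingError(PhotolimError):
    """A treatment cell has no same-day control to reference."""


class ScenarioError(PhotolimError):
    """Synthetic-data generation failed for a scenario cell."""
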