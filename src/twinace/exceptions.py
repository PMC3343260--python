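"""Exception hierarchy."""


class TwinaceError(Exception):
    """Base class for all package errors."""


class InvariantViolationError(TwinaceError, ValueError):
    """A domain-type invariant (e.g. unit liability variance) is violated."""


class CollinearityError(TwinaceError, ValueError):
    """Covariate design matrix is rank deficient.

    Carries the names of the offending (linearly dependent) columns.
    """

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"rank-deficient design; dependent columns: {self.columns}"
        )


class DegenerateBinningError(TwinaceError, ValueError):
    """Too few distinct values to form the requested number of classes."""


class ExhaustionError(TwinaceError, RuntimeError):
    """An ascertainment frame cell cannot be filled from the population.

    Carries the identity of the unfilled cell.
    """

    def __init__(self, cell, needed, available):
        self.cell = cell
        self.needed = needed
        self.available = available
        super().__init__(
            f"cannot fill ascertainment cell {cell}: "
            f"need {needed}, only {available} available"
        )


class ConvergenceError(TwinaceError, RuntimeError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, message, best=None):
        self.best = best
        super().__init__(message)


class IncompleteResultsError(TwinaceError, ValueError):
    """A report formatter was handed results with required fields missing."""
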