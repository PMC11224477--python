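"""Exception hierarchy shared across the package."""


class GrainfillError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GrainfillError, ValueError):
    """Logistic parameters outside the valid domain (A, B, C must be > 0)."""


class DegeneratePartitionError(GrainfillError, ValueError):
    """Phase partition undefined: ln(B) <= offset, the gradual phase would
    start before flowering (t1 <= 0)."""


class DataValidationError(GrainfillError, ValueError):
    """Malformed or inconsistent input data (tables, series, configs)."""


class UnbalancedDesignError(DataValidationError):
    """Split-plot ANOVA requires a balanced tillage x variety x replicate
    layout; unbalanced data are rejected rather than approximated."""


class FitError(GrainfillError, RuntimeError):
    """Curve fitting could not be set up (too few points, degenerate
    linearization). Non-convergence of a well-posed fit is NOT an error:
    it is reported via LogisticFit.converged."""


class DegenerateFitError(GrainfillError, ValueError):
    """A fitted auxiliary model has no usable optimum (e.g. a convex
    quadratic where a rate peak was requested)."""
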