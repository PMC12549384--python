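"""Exception hierarchy shared across the package."""


class DiefillError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DiefillError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class UsageError(DiefillError, ValueError):
    """An operation was called with structurally invalid input (empty,
    wrong machine kind, duplicate grid cell, ...)."""


class ConstraintError(DiefillError, ValueError):
    """A requested profile or configuration is geometrically infeasible."""


class AnalysisError(DiefillError, RuntimeError):
    """A report or dataset cannot be analysed (e.g. empty stationary window)."""


class NumericalError(DiefillError, RuntimeError):
    """The ODE solver failed to converge or a solution violates its bounds."""
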