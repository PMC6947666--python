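"""Exception hierarchy for helistent.

All errors raised on bad user input derive from :class:`ValidationError`
(a ``ValueError``), so callers can catch one type at the CLI boundary.
Solver failures derive from :class:`SolverError` (a ``RuntimeError``).
"""


class ValidationError(ValueError):
    """Invalid input: out-of-range parameter, unknown unit, malformed config."""


class SolverError(RuntimeError):
    """A numerical routine failed to converge or hit an inconsistent state."""


class InfeasibleGeometryError(SolverError):
    """The pitch quartic has no positive real root for the requested diameter."""

    def __init__(self, message: str, roots=None):
        super().__init__(message)
        self.roots = roots


class NoSolutionError(SolverError):
    """A design-criterion bracket does not straddle the target value."""


class NoFitError(ValidationError):
    """No available stent diameter is large enough for the target airway."""
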