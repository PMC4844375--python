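"""Exception hierarchy.

All package errors derive from :class:`PhytonetError` so callers can catch
one base class; each also derives from the closest builtin so untargeted
``except ValueError`` style handling keeps working.
"""


class PhytonetError(Exception):
    """Base class for all phytonet errors."""


class ValidationError(PhytonetError, ValueError):
    """A domain object violates its invariants (bad network config, bad scenario)."""


class DegenerateInputError(PhytonetError, ValueError):
    """Input is structurally valid but statistically degenerate (constant column)."""


class InsufficientDataError(PhytonetError, ValueError):
    """Too few complete observations for the requested statistic."""


class DomainError(PhytonetError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class FitError(PhytonetError, RuntimeError):
    """Nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
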