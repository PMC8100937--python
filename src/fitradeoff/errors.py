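"""Exception types shared across the package."""

from __future__ import annotations


class FITradeoffError(Exception):
    """Base class for all package-specific errors."""


class ProblemValidationError(FITradeoffError):
    """A decision problem violates its structural invariants.

    Collects *all* violations found, not just the first, so callers can
    report everything wrong with an input file at once.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid decision problem:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class DegenerateColumnError(FITradeoffError):
    """A criterion column has zero observed range, so an observed-range
    value function is undefined."""


class InfeasibleWeightSpaceError(FITradeoffError):
    """An LP query was posed against a weight space with no feasible point."""


class InconsistentAnswersError(FITradeoffError):
    """A decision maker's answer contradicts the constraints accumulated so
    far (the weight space became empty)."""

    def __init__(self, message: str, statement=None):
        self.statement = statement
        super().__init__(message)
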