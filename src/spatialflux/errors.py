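"""Exception types shared across the package."""

from __future__ import annotations


class InvalidParameterError(ValueError):
    """A model parameter violates its physical or contractual constraints."""


class UnknownPresetError(KeyError):
    """Requested parameter preset does not exist."""


class ConvergenceError(RuntimeError):
    """A nonlinear solve failed to converge.

    Carries the last residual (and, for the iterative solvers, the residual
    history) for diagnosis.
    """

    def __init__(self, message: str, residual=None, history=None):
        super().__init__(message)
        self.residual = residual
        self.history = list(history) if history is not None else None


class NotConvergedError(RuntimeError):
    """A metric was requested from a solution that is not flagged converged."""
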