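"""Exception hierarchy for gutsim.

``DomainError`` flags physically meaningless inputs (negative viscosity,
zero half-time, ...), ``ConfigurationError`` flags malformed run
configurations, and ``SolverError`` wraps numerical failures of the
PDE integrator, carrying the last good state for post-mortem.
"""

from __future__ import annotations


class GutsimError(Exception):
    """Base class for all gutsim errors."""


class DomainError(GutsimError, ValueError):
    """An input lies outside the physically meaningful domain.

    The message names the offending field and the received value.
    """


class ConfigurationError(GutsimError, ValueError):
    """A run configuration is structurally invalid (unknown key, bad
    unit, grid too coarse, missing block required by the chosen model)."""


class SolverError(GutsimError, RuntimeError):
    """The time integrator failed.

    Attributes
    ----------
    last_state : numpy.ndarray or None
        State vector at the last successfully accepted step.
    diagnostics : dict
        Integrator message and step statistics.
    """

    def __init__(self, message, last_state=None, diagnostics=None):
        super().__init__(message)
        self.last_state = last_state
        self.diagnostics = diagnostics or {}
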