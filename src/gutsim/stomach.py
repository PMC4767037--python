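"""Gastric compartment: a perfectly mixed reservoir emptying exponentially.

The stomach holds the swallowed liquid meal and delivers it to the small
intestine through first-order decay with rate constant gamma = ln2/t_half
(no lag phase, no secretion volume).  Starch and glucose co-present in a
meal empty with the same gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .properties import EmptyingParams


@dataclass(frozen=True)
class StomachState:
    """Snapshot of the gastric reservoir (masses in g, time in s)."""

    glucose_mass: float = 0.0
    starch_mass: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.glucose_mass < 0 or self.starch_mass < 0:
            raise DomainError(
                "stomach masses must be non-negative, got "
                f"glucose_mass={self.glucose_mass!r}, starch_mass={self.starch_mass!r}"
            )
        if self.time < 0:
            raise DomainError(f"time must be non-negative, got {self.time!r}")


def _check_args(t, initial_mass):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError(f"t must be non-negative, got {t!r}")
    if initial_mass < 0:
        raise DomainError(f"initial_mass must be non-negative, got {initial_mass!r}")
    return t


def stomach_mass_at(t, initial_mass: float, emptying: EmptyingParams):
    """Mass remaining in the stomach at time t: M0 exp(-gamma t), g.

    Exact closed form; vectorised over t.
    """
    t = _check_args(t, initial_mass)
    out = initial_mass * np.exp(-emptying.gamma * t)
    return out if out.ndim else float(out)


def emptying_flux(t, initial_mass: float, emptying: EmptyingParams):
    """Mass flux delivered to the duodenum at time t: gamma M0 exp(-gamma t), g/s.

    Integrates to ``initial_mass`` over [0, inf).
    """
    t = _check_args(t, initial_mass)
    out = emptying.gamma * initial_mass * np.exp(-emptying.gamma * t)
    return out if out.ndim else float(out)


def emptying_curve(times, initial_mass: float, emptying: EmptyingParams):
    """Convenience table of (time_s, stomach_mass_g, flux_g_per_s) arrays."""
    times = np.asarray(times, dtype=float)
    return times, stomach_mass_at(times, initial_mass, emptying), emptying_flux(
        times, initial_mass, emptying
    )
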