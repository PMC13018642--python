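"""Stimulus-triggered liposomal release kinetics.

The encapsulated payload is released with first-order kinetics once the
external stimulus (heat or light) fires.  The instantaneous release rate is

    omega(t) = omega_R * delta * exp(-delta * t)          [mg/mL/min]

whose integral over [0, inf) recovers the total releasable payload
``omega_R``.  The dose handed to the systemic-plasma compartment is the
release accumulated between injection and release onset, scaled by the
liposome count ``xi``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stimulus",
    "ReleaseSpec",
    "DELTA_TEMPERATURE",
    "DELTA_LIGHT",
    "release_rate",
    "cumulative_release",
    "injected_dose",
]

#: First-order release constant for heat-triggered liposomes (1/min).
DELTA_TEMPERATURE = 0.0078
#: First-order release constant for light-triggered liposomes (1/min).
DELTA_LIGHT = 1.04e-4


class Stimulus(str, enum.Enum):
    """External trigger selecting the release-rate preset."""

    TEMPERATURE = "temperature"
    LIGHT = "light"

    @property
    def delta(self) -> float:
        return DELTA_TEMPERATURE if self is Stimulus.TEMPERATURE else DELTA_LIGHT


@dataclass(frozen=True)
class ReleaseSpec:
    """Parameters of a single triggered-release bolus.

    Parameters
    ----------
    omega_R:
        Total releasable drug concentration (mg/mL).
    delta:
        First-order release rate (1/min).  If ``None``, taken from the
        ``stimulus`` preset.
    stimulus:
        Trigger type; selects the preset release constant when ``delta``
        is not given explicitly.
    xi:
        Aggregate liposome count (dimensionless scale factor, >= 1).
    R_IN:
        Interval from injection to release onset (min).
    """

    omega_R: float = 0.7
    delta: float | None = None
    stimulus: Stimulus = Stimulus.TEMPERATURE
    xi: float = 1.0
    R_IN: float = 60.0
    _delta: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        stim = Stimulus(self.stimulus)
        object.__setattr__(self, "stimulus", stim)
        delta = self.delta if self.delta is not None else stim.delta
        if not math.isfinite(self.omega_R) or self.omega_R < 0:
            raise ValueError(f"omega_R must be finite and >= 0, got {self.omega_R}")
        if not math.isfinite(delta) or delta <= 0:
            raise ValueError(f"delta must be finite and > 0, got {delta}")
        if not math.isfinite(self.R_IN) or self.R_IN < 0:
            raise ValueError(f"R_IN must be finite and >= 0, got {self.R_IN}")
        if not math.isfinite(self.xi) or self.xi < 1:
            raise ValueError(f"xi must be finite and >= 1, got {self.xi}")
        object.__setattr__(self, "_delta", float(delta))
        object.__setattr__(self, "delta", float(delta))


def release_rate(t, spec: ReleaseSpec):
    """Instantaneous release rate omega(t) = omega_R * delta * exp(-delta t).

    Accepts scalars or arrays; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("release_rate requires t >= 0")
    out = spec.omega_R * spec.delta * np.exp(-spec.delta * t)
    return out if out.ndim else float(out)


def cumulative_release(t, spec: ReleaseSpec):
    """Cumulative released concentration omega_R * (1 - exp(-delta t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cumulative_release requires t >= 0")
    out = spec.omega_R * (1.0 - np.exp(-spec.delta * t))
    return out if out.ndim else float(out)


def injected_dose(spec: ReleaseSpec) -> tuple[float, float]:
    """Dose delivered to systemic plasma and the residual release rate.

    Returns
    -------
    g_f:
        xi * omega_R * (1 - exp(-delta * R_IN)) — release accumulated over
        the injection-to-onset window, the initial condition of the
        forward compartment model.
    omega_0:
        xi * omega(R_IN) — release rate remaining at onset.
    """
    g_f = spec.xi * cumulative_release(spec.R_IN, spec)
    omega_0 = spec.xi * release_rate(spec.R_IN, spec)
    return float(g_f), float(omega_0)
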