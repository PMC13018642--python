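"""Synthetic classifier-confidence traces standing in for the imaging front end.

Scenarios cover the failure modes exercised by the closed-loop robustness
study: a correct constant trace, a transient false positive, a clamped
false negative, and multiplicative-noise corruption.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Scenario", "ConfidenceTrace", "generate_trace"]


class Scenario(str, enum.Enum):
    CORRECT = "correct"
    FALSE_POSITIVE = "false_positive"
    FALSE_NEGATIVE = "false_negative"
    NOISY = "noisy"
    CUSTOM = "custom"


@dataclass(frozen=True)
class ConfidenceTrace:
    """Time-stamped confidence values in [0, 1] with step-hold semantics."""

    times: np.ndarray
    pc_values: np.ndarray
    scenario: Scenario = Scenario.CUSTOM
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pc = np.asarray(self.pc_values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pc_values", pc)
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if times.ndim != 1 or times.size == 0 or times.shape != pc.shape:
            raise ValueError("times and pc_values must be matching non-empty 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((pc < 0) | (pc > 1)) or not np.all(np.isfinite(pc)):
            raise ValueError("confidence values must lie in [0, 1]")

    def value_at(self, t: float) -> float:
        """Step interpolation: value of the most recent sample at or before t."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        i = max(0, min(i, self.times.size - 1))
        return float(self.pc_values[i])

    def __len__(self) -> int:
        return self.times.size


def generate_trace(
    scenario,
    base_level: float = 0.6,
    horizon: float = 1440.0,
    dt: float = 15.0,
    seed: int | None = None,
    *,
    theta1: float = 0.5,
    theta2: float = 0.75,
    noise_rel: float = 0.10,
    fp_window: tuple[float, float] | None = None,
    fp_level: float | None = None,
) -> ConfidenceTrace:
    """Build a confidence trace for a named scenario.

    correct:        constant ``base_level``.
    false_positive: ``base_level`` everywhere except a window (default a
                    60-min window centered in the horizon) raised above
                    ``theta2``.
    false_negative: trace clamped strictly below ``theta1``.
    noisy:          multiplicative Gaussian noise, sigma = noise_rel *
                    base_level, truncated to [0, 1].
    """
    if not 0.0 <= base_level <= 1.0:
        raise ValueError("base_level must lie in [0, 1]")
    scenario = Scenario(scenario)
    times = np.arange(0.0, horizon + 0.5 * dt, dt)
    rng = np.random.default_rng(seed)

    if scenario is Scenario.CORRECT:
        pc = np.full_like(times, base_level)
    elif scenario is Scenario.FALSE_POSITIVE:
        pc = np.full_like(times, base_level)
        if fp_window is None:
            mid = 0.5 * horizon
            fp_window = (mid - 30.0, mid + 30.0)
        hi = fp_level if fp_level is not None else max(base_level, 0.5 * (theta2 + 1.0))
        mask = (times >= fp_window[0]) & (times <= fp_window[1])
        pc[mask] = hi
    elif scenario is Scenario.FALSE_NEGATIVE:
        pc = np.minimum(np.full_like(times, base_level), 0.9 * theta1)
    elif scenario is Scenario.NOISY:
        noise = rng.normal(0.0, noise_rel * base_level, size=times.shape)
        pc = np.clip(base_level + noise, 0.0, 1.0)
    else:
        raise ValueError(f"scenario {scenario!r} requires explicit values; use ConfidenceTrace")
    return ConfidenceTrace(times=times, pc_values=pc, scenario=scenario, seed=seed)
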