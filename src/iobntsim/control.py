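"""Supervisory dose controller with layered safety safeguards.

Confidence is mapped to a discrete therapeutic stage::

    u = 0  if Pc <  theta1        (maintenance)
    u = 1  if theta1 <= Pc < theta2   (moderate)
    u = 2  if Pc >= theta2        (intensive)

The stage linearly modulates the release parameters
``omega_0(u) = omega_base (1 + alpha_g u)`` (likewise delta and R_IN), and
each decision epoch with effective stage >= 1 injects a fresh release
bolus into the systemic-plasma compartment of the forward model.

Safety is enforced in layers, none of which may ever raise mid-run:

* reactive override — stage reduced stepwise when the intracellular level
  approaches the cap ``w_safe`` (guard fraction, default 0.9) and zeroed
  at or above the cap;
* single-dose, minimum-interval and cumulative limits with an emergency
  latch;
* a predictive guard (internal-model lookahead): a proposed bolus is only
  accepted if the projected intracellular peak, assuming no further
  dosing, stays below the guard fraction of ``w_safe``.  Because each
  accepted projection dominates the realized trajectory until the next
  accepted dose, ``w5(t) <= w_safe`` holds along the whole run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .confidence import ConfidenceTrace
from .forward import FORWARD_COLUMNS, PKParameters, peak_intracellular, simulate_forward
from .release import DELTA_TEMPERATURE, ReleaseSpec, injected_dose
from .trajectory import Trajectory

__all__ = [
    "ControlGains",
    "SafetyPolicy",
    "ControlState",
    "control_law",
    "modulate_parameters",
    "safety_override",
    "default_w_safe",
    "default_policy",
    "run_closed_loop",
]


@dataclass(frozen=True)
class ControlGains:
    """Thresholds, modulation gains and baseline release parameters."""

    theta1: float = 0.5
    theta2: float = 0.75
    alpha_g: float = 0.5
    beta_g: float = 0.5
    gamma_g: float = 0.5
    omega_base: float = 0.7
    delta_base: float = DELTA_TEMPERATURE
    R_base: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta1 < self.theta2 <= 1.0:
            raise ValueError("thresholds must satisfy 0 <= theta1 < theta2 <= 1")
        for name in ("alpha_g", "beta_g", "gamma_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega_base < 0 or self.delta_base <= 0 or self.R_base < 0:
            raise ValueError("invalid baseline release parameters")


@dataclass(frozen=True)
class SafetyPolicy:
    """Hard limits enforced by the safety layer."""

    w_safe: float
    max_single_dose: float = 5.0
    min_dose_interval: float = 15.0
    max_cumulative_dose: float = 100.0
    guard_fraction: float = 0.9
    emergency_stop: bool = False

    def __post_init__(self) -> None:
        for name in ("w_safe", "max_single_dose", "min_dose_interval",
                     "max_cumulative_dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.guard_fraction <= 1.0:
            raise ValueError("guard_fraction must lie in (0, 1]")


@dataclass
class ControlState:
    """Mutable per-run controller record."""

    u: int = 0
    dose_ledger: list[tuple[float, float, float, float, float]] = field(default_factory=list)
    # ledger rows: (time, g_f, omega_0, delta, R_IN)
    cumulative_dose: float = 0.0
    safety_events: list[tuple[float, str]] = field(default_factory=list)
    emergency_latched: bool = False

    def log(self, t: float, label: str) -> None:
        self.safety_events.append((float(t), label))

    @property
    def last_dose_time(self) -> float | None:
        return self.dose_ledger[-1][0] if self.dose_ledger else None


def control_law(pc: float, g: ControlGains) -> int:
    """Piecewise confidence-to-stage mapping with inclusive lower bounds."""
    if not (0.0 <= pc <= 1.0) or not math.isfinite(pc):
        raise ValueError(f"confidence must lie in [0, 1], got {pc!r}")
    if pc < g.theta1:
        return 0
    if pc < g.theta2:
        return 1
    return 2


def modulate_parameters(u: int, g: ControlGains) -> tuple[float, float, float]:
    """Linear stage scaling of (omega_0, delta, R_IN)."""
    if u not in (0, 1, 2):
        raise ValueError(f"stage must be 0, 1 or 2, got {u!r}")
    return (
        g.omega_base * (1.0 + g.alpha_g * u),
        g.delta_base * (1.0 + g.beta_g * u),
        g.R_base * (1.0 + g.gamma_g * u),
    )


def safety_override(
    proposed_u: int,
    w5_current: float,
    policy: SafetyPolicy,
    state: ControlState,
    t: float,
) -> int:
    """Reactive safeguards; failsafe contract — this never raises."""
    try:
        eff = int(proposed_u)
        if eff <= 0:
            return 0
        if policy.emergency_stop or state.emergency_latched:
            state.log(t, "emergency_stop")
            return 0
        if w5_current >= policy.w_safe:
            state.log(t, "w_safe_exceeded:u->0")
            return 0
        if w5_current >= policy.guard_fraction * policy.w_safe:
            eff -= 1
            state.log(t, f"guard_reduction:u->{eff}")
            if eff <= 0:
                return 0
        last = state.last_dose_time
        if last is not None and (t - last) < policy.min_dose_interval:
            state.log(t, "interval_limit:u->0")
            return 0
        if state.cumulative_dose >= policy.max_cumulative_dose:
            state.emergency_latched = True
            state.log(t, "cumulative_limit_latch:u->0")
            return 0
        return eff
    except Exception:  # pragma: no cover - failsafe default
        return 0


@lru_cache(maxsize=64)
def _open_loop_peak(p: PKParameters, g_f: float) -> float:
    traj = simulate_forward(p, g_f)
    return peak_intracellular(traj)[1]


def default_w_safe(p: PKParameters, margin: float = 1.2) -> float:
    """Cap derived from the default open-loop run: margin x its peak w5."""
    return margin * _open_loop_peak(p, p.omega_0)


def default_policy(p: PKParameters, **overrides) -> SafetyPolicy:
    overrides.setdefault("w_safe", default_w_safe(p))
    return SafetyPolicy(**overrides)


def _project_peak_w5(
    y, t, dose, horizon_end, p, rtol=1e-6, atol=1e-9, grid_dt=5.0
) -> float:
    """Peak w5 of the lookahead trajectory (state + dose, no further dosing)."""
    remaining = horizon_end - t
    if remaining <= 0:
        return float(y[4])
    traj = simulate_forward(
        p, dose, horizon=remaining, grid_dt=min(grid_dt, remaining),
        y0=y, t_start=t, rtol=rtol, atol=atol,
    )
    return float(np.max(traj["w5"]))


def run_closed_loop(
    trace: ConfidenceTrace,
    p: PKParameters,
    gains: ControlGains | None = None,
    policy: SafetyPolicy | None = None,
    *,
    decision_period: float = 15.0,
    horizon: float = 1440.0,
    grid_dt: float = 1.0,
    xi: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    predictive_guard: bool = True,
    open_loop: bool = False,
) -> tuple[Trajectory, ControlState]:
    """Run the supervisory loop over the forward plant.

    At each decision epoch the trace is read, the control law and (unless
    ``open_loop``) the safety layers determine the effective stage, and a
    stage >= 1 injects the modulated release bolus into ``w1``.  The plant
    is integrated piecewise between epochs on a uniform reporting grid.
    """
    if decision_period <= 0 or horizon <= 0:
        raise ValueError("decision_period and horizon must be > 0")
    gains = gains or ControlGains()
    policy = policy or default_policy(p)
    n_epochs = int(round(horizon / decision_period))
    state = ControlState()
    y = np.zeros(6)
    times = [0.0]
    states = [y.copy()]
    u_grid = [0]
    pc_grid = [trace.value_at(0.0)]
    events: list[tuple[float, str]] = []

    for k in range(n_epochs):
        t = k * decision_period
        pc = trace.value_at(t)
        proposed = control_law(pc, gains)
        if open_loop:
            eff = proposed
        else:
            eff = safety_override(proposed, y[4], policy, state, t)
        dose = 0.0
        om0 = dlt = rin = 0.0
        while eff >= 1:
            om0, dlt, rin = modulate_parameters(eff, gains)
            g_f, _ = injected_dose(ReleaseSpec(omega_R=om0, delta=dlt, R_IN=rin, xi=xi))
            if open_loop:
                dose = g_f
                break
            if g_f > policy.max_single_dose:
                state.log(t, f"single_dose_limit:u->{eff - 1}")
                eff -= 1
                continue
            if state.cumulative_dose + g_f > policy.max_cumulative_dose:
                state.emergency_latched = True
                state.log(t, "cumulative_limit_latch:u->0")
                eff = 0
                break
            if predictive_guard:
                proj = _project_peak_w5(y, t, g_f, horizon, p)
                if proj > policy.guard_fraction * policy.w_safe:
                    state.log(t, f"predictive_guard:u->{eff - 1}")
                    eff -= 1
                    continue
            dose = g_f
            break
        state.u = max(eff, 0)
        if dose > 0:
            state.dose_ledger.append((t, dose, om0, dlt, rin))
            state.cumulative_dose += dose
            events.append((t, f"dose:{dose:.6g}"))
        seg = simulate_forward(
            p, dose, horizon=decision_period, grid_dt=grid_dt,
            y0=y, t_start=t, rtol=rtol, atol=atol,
        )
        y = seg.states[-1].copy()
        times.extend(seg.times[1:])
        states.extend(seg.states[1:])
        u_grid.extend([state.u] * (len(seg) - 1))
        pc_grid.extend([pc] * (len(seg) - 1))

    traj = Trajectory(
        times=np.array(times),
        states=np.array(states),
        columns=FORWARD_COLUMNS,
        events=events + [(t, lbl) for t, lbl in state.safety_events],
        aux={"u": np.array(u_grid), "pc": np.array(pc_grid)},
    )
    return traj, state
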