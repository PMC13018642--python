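"""Forward-path five-compartment transport model.

State vector (all mg/mL-equivalent concentrations):

    w1    systemic plasma
    w2    tumor plasma
    w3    peripheral exchange compartment
    w4    tumor extracellular extravascular space (EES)
    w5    tumor intracellular space
    w_el  cumulative eliminated mass

Dynamics::

    dw1 = -(k12 + k10) w1 + k21 w3
    dw3 =  k12 w1 - k21 w3
    dw2 = (-ps w2 U + ps w4 Ue) / vp_t - Fpv_t w2 + Fpv_t w1
    dw4 = ( ps w2 U - ps w4 Ue) / ve_t - uptake(w4 Ue, w5)
    dw5 = uptake(w4, w5)
    dw_el = k10 w1

with the cellular uptake combining a linear and a saturable carrier term::

    uptake(x, w5) = k3wi * (k1wi x + k2wi x / (kiwi + x) - k5wi w5)

A variant that places the linear term inside the saturable denominator is
selectable with ``eq15_literal=True`` for comparison; the canonical form
above is the default (the exchange term between EES and cells is otherwise
asymmetric for no physical reason).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

from .trajectory import Trajectory

__all__ = [
    "PKParameters",
    "SA_RANGES",
    "METADATA_CONSTANTS",
    "FORWARD_COLUMNS",
    "forward_rhs",
    "simulate_forward",
    "explicit_euler_forward",
    "two_compartment_closed_form",
    "peak_intracellular",
]

FORWARD_COLUMNS = ("w1", "w2", "w3", "w4", "w5", "w_el")

#: Per-parameter (low, high) sensitivity-analysis bounds.
SA_RANGES: dict[str, tuple[float, float]] = {
    "omega_0": (0.5, 0.9),
    "k12": (7.5e-4, 1.1e-2),
    "k10": (1.5e-3, 3.0e-3),
    "k21": (5.0e-5, 1.0e-4),
    "k1wi": (1.8, 2.7),
    "k2wi": (0.036, 0.054),
    "k3wi": (2.2e-3, 3.4e-3),
    "k5wi": (8.0, 12.0),
    "kiwi": (4.2e-3, 6.4e-3),
    "U_Dox": (0.8, 1.0),
    "ps": (3.9e-3, 5.9e-3),
    "Fpv_t": (0.24, 0.36),
    "vp_t": (0.06, 0.09),
    "ve_t": (0.36, 0.54),
    "U_Dox_e": (0.8, 1.0),
}

#: Constants carried for reporting only — they enter no implemented equation.
METADATA_CONSTANTS = {
    "cumulative_dose_mg": 0.85,
    "atp_uM": 40.0,
    "michaelis_uM": 15.0,
    "bounding_molecules_uM": 0.7,
    "temperature_C": 37.0,
}

_RATE_FIELDS = (
    "k12", "k21", "k10", "ps", "Fpv_t",
    "k1wi", "k2wi", "k3wi", "k5wi", "kiwi",
)


@dataclass(frozen=True)
class PKParameters:
    """Forward-path rate/volume/binding constants (all rates 1/min)."""

    k12: float = 9.4e-3
    k21: float = 7.052e-5
    k10: float = 2.1e-3
    ps: float = 4.9e-3
    Fpv_t: float = 0.30
    vp_t: float = 0.0745
    ve_t: float = 0.454
    U_Dox: float = 1.0
    U_Dox_e: float = 1.0
    k1wi: float = 2.257
    k2wi: float = 0.0452
    k3wi: float = 2.806e-3
    k5wi: float = 10.0
    kiwi: float = 5.29e-3
    omega_0: float = 0.7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("vp_t", "ve_t"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.U_Dox < 0 or self.U_Dox_e < 0 or self.omega_0 < 0:
            raise ValueError("binding factors and omega_0 must be >= 0")

    def replace(self, **kwargs) -> "PKParameters":
        return replace(self, **kwargs)

    @property
    def sa_ranges(self) -> dict[str, tuple[float, float]]:
        return dict(SA_RANGES)


def _uptake(x: float, w5: float, p: PKParameters) -> float:
    return p.k3wi * (p.k1wi * x + p.k2wi * x / (p.kiwi + x) - p.k5wi * w5)


def _uptake_literal(x: float, w5: float, p: PKParameters) -> float:
    # Variant with the linear term inside the Michaelis denominator.
    return p.k3wi * ((p.k1wi * x + p.k2wi * x) / (p.kiwi + x) - p.k5wi * w5)


def _rhs(t, y, p: PKParameters, literal: bool):
    w1, w2, w3, w4, w5, _ = y
    x2 = w2 * p.U_Dox
    x4 = w4 * p.U_Dox_e
    upt = _uptake_literal if literal else _uptake
    dw1 = -(p.k12 + p.k10) * w1 + p.k21 * w3
    dw3 = p.k12 * w1 - p.k21 * w3
    dw2 = (-p.ps * x2 + p.ps * x4) / p.vp_t - p.Fpv_t * w2 + p.Fpv_t * w1
    dw4 = (p.ps * x2 - p.ps * x4) / p.ve_t - upt(x4, w5, p)
    dw5 = _uptake(w4, w5, p) if not literal else _uptake_literal(w4, w5, p)
    dwel = p.k10 * w1
    return (dw1, dw2, dw3, dw4, dw5, dwel)


def forward_rhs(t: float, state, p: PKParameters, eq15_literal: bool = False):
    """Validated right-hand side of the forward compartment system.

    ``state`` is ordered as :data:`FORWARD_COLUMNS`.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ValueError("state must have 6 components (w1, w2, w3, w4, w5, w_el)")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    return np.array(_rhs(t, y, p, eq15_literal))


def simulate_forward(
    p: PKParameters,
    g_f: float,
    horizon: float = 1440.0,
    grid_dt: float = 1.0,
    *,
    y0=None,
    t_start: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    eq15_literal: bool = False,
) -> Trajectory:
    """Integrate the forward system from ``w1(0) = g_f`` (others zero).

    Returns a :class:`Trajectory` on a uniform reporting grid.  States are
    clipped to zero only within a small negativity band proportional to the
    solver tolerance; larger negativity raises.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if g_f < 0 or not math.isfinite(g_f):
        raise ValueError("g_f must be finite and >= 0")
    if y0 is None:
        y0 = np.zeros(6)
        y0[0] = g_f
    else:
        y0 = np.asarray(y0, dtype=float).copy()
        y0[0] += g_f
    n = int(round(horizon / grid_dt))
    t_eval = t_start + np.linspace(0.0, horizon, n + 1)
    sol = solve_ivp(
        _rhs, (t_start, t_start + horizon), y0,
        method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        args=(p, eq15_literal),
    )
    if not sol.success:
        raise RuntimeError(
            f"forward integration failed after {sol.t.size} accepted steps: {sol.message}"
        )
    states = sol.y.T
    neg_tol = max(1e4 * atol, 1e-8)
    if states.min() < -neg_tol:
        raise RuntimeError(
            f"state negativity {states.min():.3e} exceeds tolerance band {-neg_tol:.1e}"
        )
    states = np.clip(states, 0.0, None)
    return Trajectory(times=t_eval, states=states, columns=FORWARD_COLUMNS)


def explicit_euler_forward(
    p: PKParameters,
    g_f: float,
    horizon: float = 1440.0,
    dt: float = 1e-3,
    record_every: int = 1000,
    eq15_literal: bool = False,
) -> Trajectory:
    """Fixed-step explicit-Euler reference integrator (slow; oracle use only)."""
    n_steps = int(round(horizon / dt))
    y = [g_f, 0.0, 0.0, 0.0, 0.0, 0.0]
    times = [0.0]
    states = [tuple(y)]
    # scalar arithmetic on purpose: ~100x faster than numpy per-step here
    k12, k21, k10 = p.k12, p.k21, p.k10
    ps, Fpv, vp, ve = p.ps, p.Fpv_t, p.vp_t, p.ve_t
    U, Ue = p.U_Dox, p.U_Dox_e
    k1w, k2w, k3w, k5w, kiw = p.k1wi, p.k2wi, p.k3wi, p.k5wi, p.kiwi
    for i in range(1, n_steps + 1):
        w1, w2, w3, w4, w5, wel = y
        x2 = w2 * U
        x4 = w4 * Ue
        if eq15_literal:
            upt4 = k3w * ((k1w * x4 + k2w * x4) / (kiw + x4) - k5w * w5)
            upt5 = k3w * ((k1w * w4 + k2w * w4) / (kiw + w4) - k5w * w5)
        else:
            upt4 = k3w * (k1w * x4 + k2w * x4 / (kiw + x4) - k5w * w5)
            upt5 = k3w * (k1w * w4 + k2w * w4 / (kiw + w4) - k5w * w5)
        y = [
            w1 + dt * (-(k12 + k10) * w1 + k21 * w3),
            w2 + dt * ((-ps * x2 + ps * x4) / vp - Fpv * w2 + Fpv * w1),
            w3 + dt * (k12 * w1 - k21 * w3),
            w4 + dt * ((ps * x2 - ps * x4) / ve - upt4),
            w5 + dt * upt5,
            wel + dt * (k10 * w1),
        ]
        if i % record_every == 0:
            times.append(i * dt)
            states.append(tuple(y))
    return Trajectory(
        times=np.array(times), states=np.array(states), columns=FORWARD_COLUMNS
    )


def two_compartment_closed_form(p: PKParameters, g_f: float, t):
    """Exact bi-exponential solution of the isolated (w1, w3) pair.

    Valid when the tumor couplings are disabled (``ps = Fpv_t = 0``): the
    pair then obeys the linear system ``dw1 = -(k12+k10) w1 + k21 w3``,
    ``dw3 = k12 w1 - k21 w3`` and is solved by eigen-decomposition.  The
    repeated-eigenvalue case falls back to the limiting (defective) form.
    """
    t = np.asarray(t, dtype=float)
    a = p.k12 + p.k10
    b = p.k21
    # eigenvalues of [[-a, b], [k12, -b]]
    tr = -(a + b)
    det = a * b - b * p.k12  # = b * k10
    disc = tr * tr - 4.0 * det
    disc = max(disc, 0.0)
    sq = math.sqrt(disc)
    l1 = 0.5 * (tr + sq)
    l2 = 0.5 * (tr - sq)
    scale = max(abs(l1), abs(l2), 1e-300)
    if abs(l1 - l2) < 1e-12 * scale:
        # defective case: w = exp(l t) (I + (A - l I) t) y0
        l = l1
        e = np.exp(l * t)
        w1 = e * (g_f + (-a - l) * g_f * t)
        w3 = e * (p.k12 * g_f * t)
        return w1, w3
    # eigenvectors for y0 = (g_f, 0)
    # v_i = (b, l_i + a) spans solutions; expand y0 = c1 v1 + c2 v2
    v1 = np.array([b, l1 + a])
    v2 = np.array([b, l2 + a])
    if abs(b) < 1e-300:
        # k21 = 0: w1 decouples, w3 integrates the k12 inflow directly
        w1 = g_f * np.exp(-a * t)
        if a < 1e-300:
            w3 = p.k12 * g_f * t
        else:
            w3 = p.k12 * g_f / a * (1.0 - np.exp(-a * t))
        return w1, w3
    M = np.column_stack([v1, v2])
    c = np.linalg.solve(M, np.array([g_f, 0.0]))
    e1 = np.exp(l1 * t)
    e2 = np.exp(l2 * t)
    w1 = c[0] * v1[0] * e1 + c[1] * v2[0] * e2
    w3 = c[0] * v1[1] * e1 + c[1] * v2[1] * e2
    return w1, w3


def peak_intracellular(traj: Trajectory) -> tuple[float, float]:
    """Time and value of the maximum intracellular concentration ``w5``.

    Ties broken by the earliest time (``argmax`` semantics).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    w5 = traj["w5"]
    i = int(np.argmax(w5))
    return float(traj.times[i]), float(w5[i])
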