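"""Reverse-path signaling: sensor compartments, reporter chain, light output.

A bio-nanosensor releases a molecular burst ``s0`` into its local
compartment ``v2``; exchange with systemic plasma ``v1`` follows a linear
two-compartment model with receiver absorption ``k1`` and elimination
``k10``::

    g_r  = k1 * v1
    dv1  = k21_r * v2 - (k12_r + k10 + k1) * v1
    dv2  = k12_r * v1 - k21_r * v2

The receiver output drives a canonical two-stage reporter-expression chain
(transcription then translation, first-order degradation)::

    dm  = kr * mu * g_r - gamma_r * m
    dLU = kp * m - gamma_p * LU

and the emitted light intensity is ATP-limited Michaelis–Menten in the
luciferase level, with optional additive Gaussian sensor noise::

    I = alpha_l * LU * a_tp / (alpha_M + a_tp) + N(0, sigma2)

The light-output functional form is a reconstruction (the source material
defers it to prior experimental work) and is injectable via
``light_output`` so alternative kinetics can be swapped in.

Expression/degradation constants are quoted per hour in the source
material; :meth:`ReverseParameters.default` converts them to 1/min at load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

from .trajectory import Trajectory

__all__ = [
    "ReverseParameters",
    "REVERSE_COLUMNS",
    "per_hour_to_per_min",
    "per_min_to_per_hour",
    "reverse_rhs",
    "receiver_output",
    "simulate_reverse",
    "bioluminescence_intensity",
    "threshold_decision",
    "reverse_sweep",
]

REVERSE_COLUMNS = ("v1", "v2", "m", "LU")


def per_hour_to_per_min(rate_per_h: float) -> float:
    return rate_per_h / 60.0


def per_min_to_per_hour(rate_per_min: float) -> float:
    return rate_per_min * 60.0


@dataclass(frozen=True)
class ReverseParameters:
    """Reverse-path constants, all rates normalized to 1/min.

    Construct with :meth:`default` to apply the per-hour -> per-min
    conversion of the expression-chain constants.
    """

    k12_r: float = 0.103e-2
    k21_r: float = 0.373
    k1: float = 0.1e-2
    k10: float = 2.1e-3
    s0: float = 8.0
    mu: float = 1.0
    kr: float = per_hour_to_per_min(0.1e2)
    kp: float = per_hour_to_per_min(1.5e2)
    gamma_r: float = per_hour_to_per_min(0.1005e2)
    gamma_p: float = per_hour_to_per_min(0.0415e2)
    alpha_M: float = 15.0
    alpha_l: float = 0.044
    a_tp: float = 40.0
    sigma2: float = 0.05
    I0: float = 0.007e2

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if f.name not in ("I0",) and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if self.I0 <= 0:
            raise ValueError("I0 must be > 0")

    @classmethod
    def default(
        cls,
        *,
        kr_per_h: float = 0.1e2,
        kp_per_h: float = 1.5e2,
        gamma_r_per_h: float = 0.1005e2,
        gamma_p_per_h: float = 0.0415e2,
        **kwargs,
    ) -> "ReverseParameters":
        """Build parameters from per-hour expression constants."""
        return cls(
            kr=per_hour_to_per_min(kr_per_h),
            kp=per_hour_to_per_min(kp_per_h),
            gamma_r=per_hour_to_per_min(gamma_r_per_h),
            gamma_p=per_hour_to_per_min(gamma_p_per_h),
            **kwargs,
        )

    def replace(self, **kwargs) -> "ReverseParameters":
        return replace(self, **kwargs)


def receiver_output(v1, p: ReverseParameters):
    """Receiver molecular flux g_r = k1 * v1."""
    v1 = np.asarray(v1, dtype=float)
    if np.any(v1 < 0):
        raise ValueError("v1 must be >= 0")
    out = p.k1 * v1
    return out if out.ndim else float(out)


def _rhs(t, y, p: ReverseParameters):
    v1, v2, m, LU = y
    g_r = p.k1 * v1
    dv1 = p.k21_r * v2 - (p.k12_r + p.k10 + p.k1) * v1
    dv2 = p.k12_r * v1 - p.k21_r * v2
    dm = p.kr * p.mu * g_r - p.gamma_r * m
    dLU = p.kp * m - p.gamma_p * LU
    return (dv1, dv2, dm, dLU)


def reverse_rhs(t: float, state, p: ReverseParameters):
    """Validated right-hand side; state ordered (v1, v2, m, LU)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise ValueError("state must have 4 components (v1, v2, m, LU)")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    return np.array(_rhs(t, y, p))


def default_light_output(LU, p: ReverseParameters):
    """ATP-limited Michaelis–Menten light yield (noiseless)."""
    return p.alpha_l * np.asarray(LU, dtype=float) * p.a_tp / (p.alpha_M + p.a_tp)


def bioluminescence_intensity(LU, p: ReverseParameters, rng=None, light_output=None):
    """Light intensity for luciferase level(s) ``LU`` with optional noise.

    Noise is additive zero-mean Gaussian of variance ``p.sigma2``; pass
    ``rng=None`` or set ``sigma2 = 0`` for the noiseless value.
    """
    LU = np.asarray(LU, dtype=float)
    if np.any(LU < 0):
        raise ValueError("LU must be >= 0")
    fn = light_output or default_light_output
    out = np.asarray(fn(LU, p), dtype=float)
    if rng is not None and p.sigma2 > 0:
        out = out + rng.normal(0.0, math.sqrt(p.sigma2), size=out.shape)
    return out if out.ndim else float(out)


def threshold_decision(I, I0: float):
    """Binary receiver decision: 1 iff I >= I0 (boundary inclusive)."""
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("intensity must be finite")
    out = (I >= I0).astype(int)
    return out if out.ndim else int(out)


def simulate_reverse(
    p: ReverseParameters,
    horizon: float = 600.0,
    grid_dt: float = 1.0,
    *,
    rng=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    light_output=None,
) -> Trajectory:
    """Integrate the reverse chain from ``v2(0) = s0`` and attach I and c_r.

    The intensity channel ``I`` (with noise if ``rng`` given) and the
    decision bit stream ``c_r`` are stored as aux channels.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    y0 = np.array([0.0, p.s0, 0.0, 0.0])
    n = int(round(horizon / grid_dt))
    t_eval = np.linspace(0.0, horizon, n + 1)
    sol = solve_ivp(_rhs, (0.0, horizon), y0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol, args=(p,))
    if not sol.success:
        raise RuntimeError(f"reverse integration failed: {sol.message}")
    states = sol.y.T
    neg_tol = max(1e4 * atol, 1e-8)
    if states.min() < -neg_tol * max(1.0, p.s0):
        raise RuntimeError(f"state negativity {states.min():.3e} beyond tolerance")
    states = np.clip(states, 0.0, None)
    I = bioluminescence_intensity(states[:, 3], p, rng=rng, light_output=light_output)
    c_r = threshold_decision(I, p.I0)
    return Trajectory(times=t_eval, states=states, columns=REVERSE_COLUMNS,
                      aux={"I": I, "c_r": c_r})


def reverse_sweep(
    param_name: str,
    values,
    p: ReverseParameters,
    horizon: float = 600.0,
    grid_dt: float = 1.0,
    **kwargs,
) -> dict[float, Trajectory]:
    """Family of noiseless intensity curves, one run per parameter value."""
    if param_name not in {f.name for f in fields(ReverseParameters)}:
        raise KeyError(f"unknown reverse parameter {param_name!r}")
    out: dict[float, Trajectory] = {}
    for v in values:
        pv = p.replace(**{param_name: float(v)})
        out[float(v)] = simulate_reverse(pv, horizon, grid_dt, rng=None, **kwargs)
    return out
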