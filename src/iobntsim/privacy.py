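"""Chaotic-map privacy layer: keystream masking, entropy scoring,
privacy-budget perturbation and key authentication.

The shared secret is a quadratic-map triple (alpha, beta, x0) iterated as

    x_{n+1} = alpha * x_n * (1 - x_n) + beta

whose orbit (in the chaotic regime, e.g. alpha ~ 3.99, beta = 0) is the
keystream.  Messages scaled to [0, 1] are masked additively modulo 1.  To
make the round trip bit-exact for every float64 input, the modular
addition is carried out on a fixed dyadic grid fine enough (2**-1140) to
represent any double in [0, 1] exactly; ciphertexts are therefore Python
integers (serialize as decimal strings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "ChaoticKey",
    "PrivacyBudget",
    "chaotic_step",
    "keystream",
    "encode",
    "decode",
    "stream_entropy",
    "privacy_perturb",
    "authenticate",
    "auth_auc",
    "detection_auc_vs_epsilon",
]

# 2**-1140 grid: any float64 in [0, 1] (down to subnormals) times 2**1140
# is an exact integer, so quantization is lossless.
_QBITS = 1140
_SCALE = 1 << _QBITS
_MOD = _SCALE + 1  # lets the endpoint 1.0 coexist with 0.0


@dataclass(frozen=True)
class ChaoticKey:
    """Shared-secret triple for the quadratic map."""

    alpha_key: float = 3.99
    beta_key: float = 0.0
    x0: float = 0.3141592653589793

    def __post_init__(self) -> None:
        if not (0.0 < self.x0 < 1.0):
            raise ValueError("x0 must lie in (0, 1)")
        for v in (self.alpha_key, self.beta_key):
            if not math.isfinite(v):
                raise ValueError("key parameters must be finite")


@dataclass(frozen=True)
class PrivacyBudget:
    """Perturbation budget: larger epsilon means less noise."""

    epsilon: float
    sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be >= 0")


def chaotic_step(x: float, key: ChaoticKey) -> float:
    """One iterate of x -> alpha x (1 - x) + beta."""
    if not math.isfinite(x):
        raise ValueError("x must be finite")
    return key.alpha_key * x * (1.0 - x) + key.beta_key


def keystream(key: ChaoticKey, n: int) -> np.ndarray:
    """First ``n`` iterates of the map from ``x0`` (s_i = x_{i+1})."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty(n)
    x = key.x0
    for i in range(n):
        x = chaotic_step(x, key)
        if not math.isfinite(x):
            raise ValueError("keystream diverged; key outside the bounded regime")
        out[i] = x
    return out


def _quantize(v: float) -> int:
    # exact: Fraction(v) is the true binary rational of the double
    return int(Fraction(v) * _SCALE)


def _dequantize(q: int) -> float:
    return float(Fraction(q, _SCALE))


def encode(values, key: ChaoticKey) -> list[int]:
    """Mask [0, 1]-scaled values with the keystream, additively modulo 1.

    Returns the ciphertext as exact grid integers.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (np.any(values < 0) or np.any(values > 1) or
                        not np.all(np.isfinite(values))):
        raise ValueError("values must be finite and scaled to [0, 1]")
    if values.size == 0:
        return []
    ks = keystream(key, values.size)
    return [
        (_quantize(float(v)) + _quantize(float(s) % 1.0)) % _MOD
        for v, s in zip(values, ks)
    ]


def decode(ciphertext, key: ChaoticKey) -> np.ndarray:
    """Invert :func:`encode`; exact under the encoding key."""
    ciphertext = list(ciphertext)
    if not ciphertext:
        return np.empty(0)
    ks = keystream(key, len(ciphertext))
    out = np.empty(len(ciphertext))
    for i, (c, s) in enumerate(zip(ciphertext, ks)):
        out[i] = _dequantize((int(c) - _quantize(float(s) % 1.0)) % _MOD)
    return out


def stream_entropy(samples, n_bins: int, base: str = "nats") -> float:
    """Histogram-estimated Shannon entropy of a sample set.

    Natural log by default (``base='nats'``); ``base='bits'`` divides by
    log 2.  Bounded by ``log(n_bins)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, _ = np.histogram(samples, bins=n_bins)
    p = counts[counts > 0] / samples.size
    h = float(-np.sum(p * np.log(p)))
    if base == "bits":
        h /= math.log(2.0)
    elif base != "nats":
        raise ValueError("base must be 'nats' or 'bits'")
    return h


def privacy_perturb(values, budget: PrivacyBudget, rng) -> np.ndarray:
    """Additive zero-mean Laplace noise of scale sensitivity / epsilon."""
    values = np.asarray(values, dtype=float)
    scale = budget.sensitivity / budget.epsilon
    if scale == 0:
        return values.copy()
    return values + rng.laplace(0.0, scale, size=values.shape)


def _circular_abs(d: np.ndarray) -> np.ndarray:
    d = np.abs(d) % 1.0
    return np.minimum(d, 1.0 - d)


def authenticate(ciphertext, claimed_key: ChaoticKey, reference_preamble) -> float:
    """Score a message against a known preamble under a claimed key.

    Returns the negative mean circular decode residual over the preamble
    symbols: 0 for the true key, strictly negative otherwise.
    """
    reference_preamble = np.asarray(reference_preamble, dtype=float)
    n = reference_preamble.size
    if n == 0:
        raise ValueError("reference preamble must be non-empty")
    decoded = decode(list(ciphertext)[:n], claimed_key)
    if decoded.size < n:
        raise ValueError("ciphertext shorter than the preamble")
    return float(-np.mean(_circular_abs(decoded - reference_preamble)))


def auth_auc(legit_scores, illegit_scores) -> float:
    """ROC AUC by the rank statistic (Mann–Whitney with tie correction)."""
    a = np.asarray(legit_scores, dtype=float)
    b = np.asarray(illegit_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("scores must be finite")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    return float((r_a - a.size * (a.size + 1) / 2.0) / (a.size * b.size))


def detection_auc_vs_epsilon(
    epsilons,
    n_per_class: int = 2000,
    seed: int = 0,
    sensitivity: float = 1.0,
) -> dict[float, float]:
    """Detection quality on a fixed synthetic two-class task vs epsilon.

    Two overlapping value populations are perturbed under each budget with
    common random numbers; the AUC of the raw perturbed value as detector
    score quantifies remaining utility.
    """
    rng = np.random.default_rng(seed)
    neg = np.clip(rng.normal(0.40, 0.05, n_per_class), 0, 1)
    pos = np.clip(rng.normal(0.60, 0.05, n_per_class), 0, 1)
    unit_noise = rng.laplace(0.0, 1.0, 2 * n_per_class)
    out: dict[float, float] = {}
    for eps in epsilons:
        scale = sensitivity / float(eps)
        noised = np.concatenate([pos, neg]) + scale * unit_noise
        out[float(eps)] = auth_auc(noised[:n_per_class], noised[n_per_class:])
    return out
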