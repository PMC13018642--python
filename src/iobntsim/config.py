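"""Run-configuration loading and validation.

Configs are YAML mappings of module sections to parameter overrides; every
omitted key falls back to the built-in defaults.  Unknown keys are hard
errors (reported with their full path), while overrides outside the
tabulated sensitivity ranges only warn — the ranges are guidance, not hard
bounds.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .control import ControlGains, SafetyPolicy, default_w_safe
from .deployment import DeploymentProfile
from .forward import SA_RANGES, PKParameters
from .privacy import ChaoticKey
from .release import ReleaseSpec
from .reverse import ReverseParameters

__all__ = ["RunConfig", "load_config", "config_hash", "EXPERIMENTS"]

EXPERIMENTS = (
    "forward", "reverse", "closed_loop", "monte_carlo",
    "sweep", "robustness", "privacy", "deployment",
)

_SOLVER_DEFAULTS = {"rtol": 1e-8, "atol": 1e-10, "grid_dt": 1.0,
                    "horizon": 1440.0, "method": "LSODA"}
_CONTROL_EXTRA = {"decision_period": 15.0}
_SAFETY_DEFAULTS = {"w_safe": None, "max_single_dose": 5.0,
                    "min_dose_interval": 15.0, "max_cumulative_dose": 100.0,
                    "guard_fraction": 0.9, "emergency_stop": False}
_PRIVACY_DEFAULTS = {"alpha_key": 3.99, "beta_key": 0.0, "x0": 0.3141592653589793,
                     "epsilon": 2.0, "sensitivity": 1.0}
_EXPERIMENT_DEFAULTS = {
    "name": "forward",
    "n_samples": 500,
    "n_reps": 100,
    "noise_rel": 0.10,
    "base_level": 0.6,
    "scenario": "correct",
    "sweep_param": "ps",
    "sweep_points": 5,
    "message_length": 64,
    "n_messages": 200,
}


def _defaults() -> dict:
    rel = ReleaseSpec()
    return {
        "release": {"omega_R": rel.omega_R, "delta": rel.delta,
                    "stimulus": rel.stimulus.value, "xi": rel.xi, "R_IN": rel.R_IN},
        "forward": {f.name: getattr(PKParameters(), f.name)
                    for f in fields(PKParameters)},
        "reverse": {f.name: getattr(ReverseParameters(), f.name)
                    for f in fields(ReverseParameters)},
        "control": {**{f.name: getattr(ControlGains(), f.name)
                       for f in fields(ControlGains)}, **_CONTROL_EXTRA},
        "safety": dict(_SAFETY_DEFAULTS),
        "privacy": dict(_PRIVACY_DEFAULTS),
        "deployment": {f.name: getattr(DeploymentProfile(), f.name)
                       for f in fields(DeploymentProfile)},
        "solver": dict(_SOLVER_DEFAULTS),
        "experiment": dict(_EXPERIMENT_DEFAULTS),
        "seed": 0,
    }


@dataclass
class RunConfig:
    """Validated configuration with every default filled in."""

    data: dict = field(default_factory=_defaults)

    def section(self, name: str) -> dict:
        return self.data[name]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def pk_parameters(self) -> PKParameters:
        sec = self.section("forward")
        return PKParameters(**sec)

    def release_spec(self) -> ReleaseSpec:
        return ReleaseSpec(**self.section("release"))

    def reverse_parameters(self) -> ReverseParameters:
        return ReverseParameters(**self.section("reverse"))

    def control_gains(self) -> ControlGains:
        sec = {k: v for k, v in self.section("control").items()
               if k not in _CONTROL_EXTRA}
        return ControlGains(**sec)

    def safety_policy(self) -> SafetyPolicy:
        sec = dict(self.section("safety"))
        if sec.get("w_safe") is None:
            sec["w_safe"] = default_w_safe(self.pk_parameters())
        return SafetyPolicy(**sec)

    def chaotic_key(self) -> ChaoticKey:
        sec = self.section("privacy")
        return ChaoticKey(alpha_key=sec["alpha_key"], beta_key=sec["beta_key"],
                          x0=sec["x0"])

    def deployment_profile(self) -> DeploymentProfile:
        return DeploymentProfile(**self.section("deployment"))


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise KeyError(f"unknown config key: {where}")
        if isinstance(out[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config section {where} must be a mapping")
            out[key] = _merge(out[key], value, where)
        else:
            out[key] = value
    return out


def _warn_out_of_range(forward_sec: dict) -> None:
    for name, (lo, hi) in SA_RANGES.items():
        v = forward_sec.get(name)
        if v is not None and not lo <= v <= hi:
            warnings.warn(
                f"forward.{name}={v} is outside the sensitivity range "
                f"[{lo}, {hi}]; running anyway",
                stacklevel=3,
            )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing file sections use defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise TypeError("config root must be a mapping")
        raw = loaded
    if overrides:
        raw = _merge_shallow(raw, overrides)
    data = _merge(_defaults(), raw)
    _warn_out_of_range(data["forward"])
    cfg = RunConfig(data=data)
    if data["experiment"]["name"] not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {data['experiment']['name']!r}")
    # touch every constructor so structural errors surface at load time
    cfg.pk_parameters(); cfg.release_spec(); cfg.reverse_parameters()
    cfg.control_gains(); cfg.chaotic_key(); cfg.deployment_profile()
    return cfg


def _merge_shallow(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_shallow(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the fully-resolved configuration."""
    blob = json.dumps(cfg.data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
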