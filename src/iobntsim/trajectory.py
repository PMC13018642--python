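"""Shared time-gridded trajectory record used by every simulator module."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Uniformly structured simulation output.

    Attributes
    ----------
    times:
        Strictly increasing time grid (min).
    states:
        ``(len(times), len(columns))`` matrix of state values.
    columns:
        Column names matching ``states``.
    events:
        ``(time, label)`` annotations (dose injections, safety clips, ...).
    aux:
        Extra per-time channels (e.g. control stage ``u``), same length as
        ``times``.
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    events: list[tuple[float, str]] = field(default_factory=list)
    aux: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.columns = tuple(self.columns)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.columns)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"({self.times.size}, {len(self.columns)})"
            )
        for name, arr in self.aux.items():
            if np.asarray(arr).shape[0] != self.times.size:
                raise ValueError(f"aux channel {name!r} length mismatch")

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.columns:
            return self.states[:, self.columns.index(name)]
        if name in self.aux:
            return np.asarray(self.aux[name])
        raise KeyError(name)

    def auc(self, name: str) -> float:
        """Trapezoidal area under the named channel."""
        return float(np.trapezoid(self[name], self.times))

    def to_frame(self) -> pd.DataFrame:
        data = {"time_min": self.times}
        for i, c in enumerate(self.columns):
            data[c] = self.states[:, i]
        for name, arr in self.aux.items():
            data[name] = np.asarray(arr)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        out: dict[str, float] = {}
        for c in self.columns:
            col = self[c]
            i = int(np.argmax(col))
            out[f"peak_{c}"] = float(col[i])
            out[f"t_peak_{c}"] = float(self.times[i])
            out[f"auc_{c}"] = self.auc(c)
        return out
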