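"""Acquisition/storage/throughput arithmetic for the ingestible imaging device.

Decimal (SI) byte prefixes throughout: 1 kB = 1000 B, 1 GB = 1e9 B.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DeploymentProfile", "raw_rate", "procedure_storage", "profile_report"]


@dataclass(frozen=True)
class DeploymentProfile:
    """Imaging-capsule acquisition profile."""

    width: int = 320
    height: int = 320
    bytes_per_pixel: int = 3
    fps: float = 2.5
    duration_hours: float = 8.0
    compression_ratio: float = 10.0
    storage_capacity_bytes: float = 16e9

    def __post_init__(self) -> None:
        for name in ("width", "height", "bytes_per_pixel", "fps",
                     "duration_hours", "storage_capacity_bytes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.compression_ratio < 1:
            raise ValueError("compression_ratio must be >= 1")


def raw_rate(profile: DeploymentProfile) -> dict:
    """Raw data-generation rate: width * height * bytes_per_pixel * fps."""
    bps = profile.width * profile.height * profile.bytes_per_pixel * profile.fps
    return {
        "bytes_per_second": float(bps),
        "kB_per_second": bps / 1e3,
        "GB_per_hour": bps * 3600.0 / 1e9,
    }


def procedure_storage(profile: DeploymentProfile) -> dict:
    """Compressed storage and frame count for one full procedure."""
    rr = raw_rate(profile)
    seconds = profile.duration_hours * 3600.0
    raw_total = rr["bytes_per_second"] * seconds
    stored = raw_total / profile.compression_ratio
    return {
        "frame_count": profile.fps * seconds,
        "raw_total_bytes": raw_total,
        "stored_bytes": stored,
        "stored_GB": stored / 1e9,
        "storage_utilization": stored / profile.storage_capacity_bytes,
        "fits_storage": stored <= profile.storage_capacity_bytes,
    }


def profile_report(profile: DeploymentProfile) -> dict:
    return {
        "profile": {
            "width": profile.width,
            "height": profile.height,
            "bytes_per_pixel": profile.bytes_per_pixel,
            "fps": profile.fps,
            "duration_hours": profile.duration_hours,
            "compression_ratio": profile.compression_ratio,
            "storage_capacity_bytes": profile.storage_capacity_bytes,
        },
        "raw_rate": raw_rate(profile),
        "procedure_storage": procedure_storage(profile),
    }
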