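"""Acquisition geometry of a helical-scan endoscopic OCT probe.

A side-viewing fiber probe rotates inside a transparent sheath while being
pulled back along the colon, so the beam samples the lumen wall on a helix.
:class:`ScanGeometry` ties the three index axes of the recorded data —
A-line within a B-scan (angle), B-scan within the pullback (position along
the colon), and depth sample (distance into tissue) — to physical units.

Conventions shared by every module in this package:

* depth index 0 is the first depth sample on the probe/sheath side, and
  indices increase outward into tissue;
* one B-scan per probe revolution, so the frame rate equals the rotation
  rate;
* ``axial_pixel_pitch`` is the axial sampling interval *in air* (µm); the
  tissue group refractive index converts optical to physical depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = [
    "ScanGeometry",
    "InvalidGeometryError",
    "scan_duration",
    "frame_rate",
    "bscan_pitch",
    "depth_to_physical",
]


class InvalidGeometryError(ValueError):
    """Raised when scan-geometry parameters are unphysical or inconsistent."""


@dataclass(frozen=True)
class ScanGeometry:
    """Physical acquisition parameters of one helical pullback scan.

    Parameters
    ----------
    a_line_rate : float
        Swept-source A-line (depth profile) rate, Hz.
    rotation_speed : float
        Probe rotation speed, revolutions per minute.
    pullback_speed : float
        Pullback translation speed, mm/s.
    pullback_length : float
        Total pullback distance, mm.
    a_lines_per_bscan : int
        Recorded A-lines per B-scan frame.  Stored as supplied by the
        acquisition software; it is *not* derived from ``a_line_rate`` and
        ``rotation_speed`` because recorded counts routinely disagree with
        the nominal rates.
    n_bscans : int
        Number of B-scan frames in the pullback.
    axial_pixel_pitch : float
        Depth sampling interval in air, µm per sample.
    n_depth_samples : int
        Depth samples per A-line.
    sheath_outer_radius : float
        Outer radius of the transparent protective sheath, mm.
    refractive_index : float
        Tissue group index used to convert optical depth to physical depth
        (≥ 1).  Default 1.38, typical for soft tissue.
    """

    a_line_rate: float = 100_000.0
    rotation_speed: float = 2400.0
    pullback_speed: float = 0.1
    pullback_length: float = 12.0
    a_lines_per_bscan: int = 5012
    n_bscans: int = 4050
    axial_pixel_pitch: float = 5.0
    n_depth_samples: int = 1024
    sheath_outer_radius: float = 1.15
    refractive_index: float = 1.38

    def __post_init__(self) -> None:
        for name in (
            "a_line_rate",
            "rotation_speed",
            "pullback_speed",
            "pullback_length",
            "axial_pixel_pitch",
            "sheath_outer_radius",
        ):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("a_lines_per_bscan", "n_bscans", "n_depth_samples"):
            value = getattr(self, name)
            if not (isinstance(value, (int,)) and value > 0):
                raise InvalidGeometryError(f"{name} must be a positive integer, got {value!r}")
        if self.refractive_index < 1.0:
            raise InvalidGeometryError(
                f"refractive_index must be >= 1, got {self.refractive_index!r}"
            )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScanGeometry":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidGeometryError(f"unknown geometry keys: {sorted(unknown)}")
        ints = {"a_lines_per_bscan", "n_bscans", "n_depth_samples"}
        coerced = {k: (int(v) if k in ints else float(v)) for k, v in data.items()}
        return cls(**coerced)

    def save(self, path: str | Path) -> None:
        """Write the geometry as a flat YAML (or JSON, by suffix) mapping."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ScanGeometry":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidGeometryError(f"{path} does not contain a flat mapping")
        return cls.from_dict(data)


def scan_duration(geom: ScanGeometry) -> float:
    """Total pullback acquisition time in seconds (length / speed)."""
    return geom.pullback_length / geom.pullback_speed


def frame_rate(geom: ScanGeometry) -> float:
    """B-scan frame rate in frames/s (one frame per revolution)."""
    return geom.rotation_speed / 60.0


def bscan_pitch(geom: ScanGeometry) -> float:
    """Spacing between successive B-scans along the pullback axis, µm."""
    if geom.n_bscans < 2:
        raise InvalidGeometryError("bscan_pitch needs n_bscans >= 2")
    return geom.pullback_length * 1000.0 / geom.n_bscans


def depth_to_physical(index, geom: ScanGeometry):
    """Physical depth in tissue (µm) of a depth-sample index.

    Accepts scalars or arrays; ``index × axial_pixel_pitch / refractive_index``.
    """
    import numpy as np

    index = np.asarray(index, dtype=float)
    if np.any(index < 0):
        raise InvalidGeometryError("depth index must be >= 0")
    out = index * geom.axial_pixel_pitch / geom.refractive_index
    return float(out) if out.ndim == 0 else out
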