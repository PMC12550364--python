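"""B-scan framing, log compression, polar rendering, en-face extraction.

The acquisition produces a continuous stream of A-scans while the probe
rotates and pulls back; one B-scan corresponds to one revolution.  This
module frames that stream into a volume indexed ``[bscan, a_line, depth]``,
converts intensities to dB for display/segmentation, renders individual
B-scans as circular disks resembling the physical colon cross-section, and
extracts en-face (constant depth below surface) slices from flattened
volumes.

Angular convention: A-line ``i`` maps to ``θ = 2πi / a_lines_per_bscan``,
counter-clockwise from the +x (3 o'clock) axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry

__all__ = [
    "OCTVolume",
    "frame_bscans",
    "log_compress",
    "to_polar_disk",
    "extract_enface",
]

log = logging.getLogger(__name__)


@dataclass
class OCTVolume:
    """Ordered stack of B-scans: ``data[bscan, a_line, depth]``.

    ``scale`` is ``"linear"`` (non-negative backscatter intensity) or
    ``"dB"`` (log-compressed).
    """

    data: np.ndarray
    geom: ScanGeometry
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D [bscan, a_line, depth]")
        nb, na, nd = self.data.shape
        g = self.geom
        if (nb, na, nd) != (g.n_bscans, g.a_lines_per_bscan, g.n_depth_samples):
            raise ValueError(
                f"data shape {self.data.shape} does not match geometry "
                f"({g.n_bscans}, {g.a_lines_per_bscan}, {g.n_depth_samples})"
            )
        if self.scale not in ("linear", "dB"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and self.data.size and self.data.min() < 0:
            raise ValueError("linear intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def frame_bscans(stream: np.ndarray, geom: ScanGeometry) -> OCTVolume:
    """Frame a flat A-scan stream into B-scans.

    The stream is a sequence of consecutive A-scans, each
    ``n_depth_samples`` long; the number of A-scans per B-scan is fixed by
    the rotary synchronization.  A trailing partial frame is discarded (the
    discarded A-line count is logged).
    """
    stream = np.asarray(stream).ravel()
    nd, na, nb = geom.n_depth_samples, geom.a_lines_per_bscan, geom.n_bscans
    n_alines_avail = stream.size // nd
    if n_alines_avail < na:
        raise ValueError(
            f"stream holds {n_alines_avail} A-lines; at least one frame "
            f"({na} A-lines) required"
        )
    n_frames = min(nb, n_alines_avail // na)
    used = n_frames * na * nd
    discarded = n_alines_avail - n_frames * na
    if discarded:
        log.info("frame_bscans: discarded %d trailing A-lines", discarded)
    data = stream[:used].reshape(n_frames, na, nd)
    geom_out = geom
    if n_frames != nb:
        from dataclasses import replace

        geom_out = replace(geom, n_bscans=n_frames)
    return OCTVolume(data=data, geom=geom_out, scale="linear")


def log_compress(vol: OCTVolume, floor: float = 1e-4) -> OCTVolume:
    """Convert linear intensity to dB above a noise floor.

    ``out = 20·log10(max(I, floor) / floor)``; output is ≥ 0 and strictly
    monotone in the input above the floor.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if vol.scale == "dB":
        raise ValueError("volume is already log-compressed")
    out = 20.0 * np.log10(np.maximum(vol.data, floor) / floor)
    return OCTVolume(data=out, geom=vol.geom, scale="dB")


def to_polar_disk(
    bscan: np.ndarray,
    geom: ScanGeometry,
    out_px: int,
    order: int = 1,
    background: float = 0.0,
) -> np.ndarray:
    """Render one B-scan ``[a_line, depth]`` as a circular disk image.

    The pixel at polar radius ``r`` (px) and angle ``θ`` is sampled from
    A-line ``θ / Δθ`` and depth ``r − r_sheath`` (depth 0 sits at the sheath
    outer radius) with interpolation of the given spline ``order``
    (1 = bilinear, 0 = nearest).  Pixels inside the sheath radius and beyond
    the recorded depth are set to ``background``.  The angular axis wraps.
    """
    bscan = np.asarray(bscan, dtype=float)
    na, nd = bscan.shape
    if out_px < 2 or out_px % 2:
        raise ValueError("out_px must be even and >= 2")
    r_sheath_px = geom.sheath_outer_radius * 1000.0 / geom.axial_pixel_pitch
    r_max = r_sheath_px + nd
    if out_px < 2 * r_max:
        raise ValueError(
            f"out_px = {out_px} cannot contain the maximum radius "
            f"{r_max:.0f} px (need >= {int(np.ceil(2 * r_max))})"
        )
    c = (out_px - 1) / 2.0
    y, x = np.mgrid[0:out_px, 0:out_px]
    dx = x - c
    dy = c - y  # +y up so angles run counter-clockwise in image space
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    a_coord = theta / (2.0 * np.pi) * na
    d_coord = r - r_sheath_px
    # wrap the angular axis by padding one row
    padded = np.concatenate([bscan, bscan[:1]], axis=0)
    disk = ndimage.map_coordinates(
        padded,
        [a_coord.ravel(), d_coord.ravel()],
        order=order,
        mode="constant",
        cval=background,
    ).reshape(out_px, out_px)
    disk[(d_coord < 0) | (d_coord > nd - 1)] = background
    return disk


def extract_enface(
    flat_volume: np.ndarray, depth_offset: int, background: float = 0.0
) -> np.ndarray:
    """Extract an en-face slice from a flattened volume.

    ``flat_volume`` is ``[bscan, a_line, relative depth]`` with the wall
    surface at depth row 0 (the output of flattening); the slice at
    ``depth_offset`` samples below the surface is returned as an image
    ``[bscan, a_line]``.  Offsets beyond the recorded depth yield
    ``background``.
    """
    if depth_offset < 0:
        raise ValueError("depth_offset must be >= 0")
    flat_volume = np.asarray(flat_volume)
    if flat_volume.ndim != 3:
        raise ValueError("flattened volume must be 3-D [bscan, a_line, depth]")
    if depth_offset >= flat_volume.shape[2]:
        return np.full(flat_volume.shape[:2], background, dtype=float)
    return flat_volume[:, :, depth_offset].astype(float)
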