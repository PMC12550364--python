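"""Colon-wall segmentation of endoscopic OCT B-scans.

Pipeline per B-scan (image axes ``[a_line, depth]``, dB scale):

1. Canny edge detection — speckle makes the wall interior edge-dense, so
   the wall becomes a solid component after the next two steps;
2. hole filling (background regions not reachable from the border);
3. morphological closing (dilation then erosion, disk structuring element);
4. mask building — the known sheath band is deleted, the largest connected
   component is kept, and per A-line the wall is the half-open band
   ``[top, bottom)`` between the component's first and last foreground
   sample.  A-lines whose wall starts immediately below the deleted sheath
   band are treated as being in contact with the sheath and their top is
   snapped to the sheath outer surface.  A-lines with no foreground are
   linearly interpolated across angular gaps up to a configured width,
   otherwise flagged missing (sentinel −1);
5. mask multiplication and flattening — each A-line is shifted up by its
   top boundary so the wall surface sits on row 0, then cropped; the shifts
   are stored so flattening is invertible.

All coordinates are 0-based with half-open ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, morphology

__all__ = [
    "SENTINEL",
    "SegmentationParams",
    "WallMask",
    "FlattenedBScan",
    "detect_edges",
    "fill_holes",
    "morph_refine",
    "build_wall_mask",
    "apply_mask",
    "flatten",
    "unflatten",
    "segment_bscan",
    "segment_volume",
    "flatten_volume",
]

SENTINEL = -1


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the wall-segmentation pipeline.

    Canny thresholds are relative to the maximum gradient magnitude of the
    smoothed image.  ``sheath_band_px`` is the half-open depth-row interval
    occupied by the sheath rings (plus margin) to delete before component
    selection; ``contact_row`` is the depth row of the sheath outer surface,
    where the wall top sits when tissue rests on the sheath.
    """

    sigma: float = 2.0
    low_threshold: float = 0.1
    high_threshold: float = 0.3
    se_radius: int = 3
    sheath_margin_px: int = 3
    max_gap_deg: float = 15.0
    sheath_band_px: tuple[int, int] | None = None
    contact_row: int | None = None
    contact_tol_px: int = 1


@dataclass
class WallMask:
    """Binary wall segmentation with per-A-line boundaries.

    ``mask`` is exactly the band ``[top, bottom)`` per A-line; boundaries
    are ``SENTINEL`` where no wall was found.  Arrays are 2-D for a single
    B-scan (``mask[a_line, depth]``) or 3-D for a volume.
    """

    mask: np.ndarray
    top_boundary: np.ndarray
    bottom_boundary: np.ndarray

    @property
    def empty(self) -> bool:
        return bool(np.all(self.top_boundary == SENTINEL))

    @property
    def valid(self) -> np.ndarray:
        return self.top_boundary != SENTINEL


@dataclass
class FlattenedBScan:
    """A B-scan with the wall surface aligned to row 0.

    ``shifts`` holds each A-line's original top-boundary row (SENTINEL for
    missing A-lines), so flattening is invertible for all retained rows.
    """

    image: np.ndarray  # (a_lines, crop_depth)
    shifts: np.ndarray  # (a_lines,)
    crop_depth: int
    orig_depth: int


def detect_edges(
    bscan: np.ndarray,
    sigma: float = 2.0,
    low_threshold: float = 0.1,
    high_threshold: float = 0.3,
) -> np.ndarray:
    """Canny edge map of a dB B-scan with thresholds relative to the
    maximum gradient magnitude."""
    if not (0.0 <= low_threshold < high_threshold <= 1.0):
        raise ValueError("need 0 <= low < high <= 1 (relative thresholds)")
    bscan = np.asarray(bscan, dtype=float)
    gmax = float(filters.sobel(filters.gaussian(bscan, sigma=sigma)).max())
    if gmax == 0.0:
        return np.zeros(bscan.shape, dtype=bool)
    return feature.canny(
        bscan,
        sigma=sigma,
        low_threshold=low_threshold * gmax,
        high_threshold=high_threshold * gmax,
    )


def fill_holes(binary: np.ndarray) -> np.ndarray:
    """Set background regions not reachable from the image border to
    foreground."""
    return ndimage.binary_fill_holes(np.asarray(binary, dtype=bool))


def morph_refine(binary: np.ndarray, se_radius: int = 3) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a disk."""
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    return morphology.closing(
        np.asarray(binary, dtype=bool), morphology.disk(se_radius)
    )


def _interp_gaps(values: np.ndarray, valid: np.ndarray, max_run: int) -> np.ndarray:
    """Linearly interpolate sentinel runs no longer than ``max_run``,
    treating the A-line axis as circular."""
    n = len(values)
    out = values.astype(float).copy()
    if valid.all() or not valid.any():
        return out
    idx = np.arange(n)
    missing = ~valid
    # find circular runs of missing entries
    lab, nlab = ndimage.label(missing)
    # merge wrap-around run
    if missing[0] and missing[-1] and nlab > 1:
        lab[lab == lab[-1]] = lab[0]
    for run_id in np.unique(lab[lab > 0]):
        run = idx[lab == run_id]
        if len(run) > max_run:
            continue
        # circular neighbors
        left = (run.min() - 1) % n if not missing[(run.min() - 1) % n] else None
        right = (run.max() + 1) % n if not missing[(run.max() + 1) % n] else None
        if left is None or right is None:
            continue
        # positions along the circle relative to left neighbor
        span = (right - left) % n
        if span == 0:
            out[run] = values[left]
            continue
        for r in run:
            t = ((r - left) % n) / span
            out[r] = (1 - t) * values[left] + t * values[right]
    return out


def build_wall_mask(
    refined: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    a_lines_per_rev: int | None = None,
    walk_image: np.ndarray | None = None,
) -> WallMask:
    """Extract the wall band from a refined binary image.

    The sheath band (if configured) is deleted, the largest remaining
    8-connected component kept (ties broken toward smaller mean depth),
    boundaries read off per A-line, the sheath-contact correction applied,
    and short angular gaps interpolated.  An empty result is returned
    flagged (all-sentinel boundaries), never raised.
    """
    refined = np.asarray(refined, dtype=bool)
    na, nd = refined.shape
    if a_lines_per_rev is None:
        a_lines_per_rev = na
    work = refined.copy()
    band = params.sheath_band_px
    if band is not None:
        lo, hi = band
        work[:, max(lo, 0) : min(hi, nd)] = False

    top = np.full(na, SENTINEL, dtype=int)
    bottom = np.full(na, SENTINEL, dtype=int)
    lab, nlab = ndimage.label(work, structure=np.ones((3, 3), dtype=int))
    if nlab > 0:
        sizes = ndimage.sum_labels(work, lab, index=np.arange(1, nlab + 1))
        best = sizes.max()
        cand = np.flatnonzero(sizes == best) + 1
        if len(cand) > 1:
            depth_idx = np.broadcast_to(np.arange(nd), work.shape)
            means = ndimage.mean(depth_idx, lab, index=cand)
            comp = int(cand[np.argmin(means)])
        else:
            comp = int(cand[0])
        sel = lab == comp
        has = sel.any(axis=1)
        first = np.argmax(sel, axis=1)
        last = nd - 1 - np.argmax(sel[:, ::-1], axis=1)
        top[has] = first[has]
        bottom[has] = last[has] + 1  # half-open

        if band is not None and params.contact_row is not None:
            # Recover surface rows hidden by the deleted band: walk each
            # A-line upward through the pre-deletion image while foreground
            # is contiguous, down to the first row below the sheath outer
            # ring.  A wall contiguous with (or within a couple of rows of)
            # the ring is resting on the sheath, so its surface is the
            # sheath outer radius.
            ring_end = min(band[1], nd) - params.sheath_margin_px
            # The walk runs on the pre-closing image when available: closing
            # can bridge the sheath ring to a slightly detached wall, which
            # would snap genuinely detached surfaces onto the sheath.
            # Lateral dilation lets neighbouring A-lines vouch for
            # contiguity, so sparse speckle edges do not block the walk,
            # while genuine (multi-row, all-angle) detachment gaps still do.
            basis = refined if walk_image is None else np.asarray(walk_image, bool)
            walkable = ndimage.binary_dilation(
                basis, structure=np.ones((9, 3), dtype=bool)
            )
            for a in np.flatnonzero(has):
                r = int(first[a])
                while r - 1 >= ring_end and walkable[a, r - 1]:
                    r -= 1
                if r <= ring_end + params.contact_tol_px:
                    top[a] = params.contact_row
                else:
                    # the dilated walk gives a lower envelope (neighbours can
                    # drag it up steep slopes); refine on the A-line's own
                    # undilated column
                    while r < first[a] and not basis[a, r]:
                        r += 1
                    top[a] = r

    valid = top != SENTINEL
    if valid.any() and not valid.all():
        max_run = int(round(params.max_gap_deg / 360.0 * a_lines_per_rev))
        top_f = _interp_gaps(top, valid, max_run)
        bot_f = _interp_gaps(bottom, valid, max_run)
        fixed = (~valid) & np.isfinite(top_f) & (top_f != SENTINEL) & (bot_f != SENTINEL)
        # only entries actually interpolated differ from sentinel
        interp = (~valid) & (top_f != SENTINEL)
        top = np.where(interp, np.round(top_f), top).astype(int)
        bottom = np.where(interp, np.round(bot_f), bottom).astype(int)
        del fixed

    mask = np.zeros((na, nd), dtype=np.uint8)
    d = np.arange(nd)
    ok = top != SENTINEL
    mask[ok] = ((d >= top[ok, None]) & (d < bottom[ok, None])).astype(np.uint8)
    return WallMask(mask=mask, top_boundary=top, bottom_boundary=bottom)


def apply_mask(bscan: np.ndarray, wall: WallMask) -> np.ndarray:
    """Elementwise product of the image with the binary wall mask."""
    bscan = np.asarray(bscan)
    if bscan.shape != wall.mask.shape:
        raise ValueError(f"shape mismatch: {bscan.shape} vs {wall.mask.shape}")
    return bscan * wall.mask


def flatten(
    bscan: np.ndarray, wall: WallMask, crop_depth: int, background: float = 0.0
) -> FlattenedBScan:
    """Shift each A-line up by its top boundary and crop.

    Missing A-lines (sentinel boundaries) are filled with ``background``.
    A ``crop_depth`` beyond the image depth is clipped with a warning.
    """
    bscan = np.asarray(bscan)
    na, nd = bscan.shape
    if crop_depth > nd:
        warnings.warn(
            f"crop_depth {crop_depth} exceeds depth range {nd}; clipping",
            stacklevel=2,
        )
        crop_depth = nd
    out = np.full((na, crop_depth), background, dtype=float)
    shifts = wall.top_boundary.copy()
    for i in range(na):
        s = shifts[i]
        if s == SENTINEL:
            continue
        n_keep = min(crop_depth, nd - s)
        out[i, :n_keep] = bscan[i, s : s + n_keep]
    return FlattenedBScan(image=out, shifts=shifts, crop_depth=crop_depth, orig_depth=nd)


def unflatten(flat: FlattenedBScan, background: float = 0.0) -> np.ndarray:
    """Invert :func:`flatten`, restoring every retained pixel to its
    original depth row."""
    na = flat.image.shape[0]
    out = np.full((na, flat.orig_depth), background, dtype=float)
    for i in range(na):
        s = flat.shifts[i]
        if s == SENTINEL:
            continue
        n_keep = min(flat.crop_depth, flat.orig_depth - s)
        out[i, s : s + n_keep] = flat.image[i, :n_keep]
    return out


def segment_bscan(
    bscan_db: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> WallMask:
    """Run the full edge → fill → close → mask pipeline on one dB B-scan."""
    edges = detect_edges(
        bscan_db, params.sigma, params.low_threshold, params.high_threshold
    )
    filled = fill_holes(edges)
    refined = morph_refine(filled, params.se_radius)
    # brightness mask for the top-boundary walk: tissue and sheath are
    # far above the background level, detachment gaps are dark
    bscan_db = np.asarray(bscan_db, dtype=float)
    if bscan_db.max() > bscan_db.min():
        bright = bscan_db > filters.threshold_otsu(bscan_db)
    else:
        bright = None
    return build_wall_mask(refined, params, walk_image=bright)


def segment_volume(vol_db, params: SegmentationParams = SegmentationParams()) -> WallMask:
    """Segment every B-scan of a dB volume; returns stacked 3-D WallMask."""
    data = vol_db.data if hasattr(vol_db, "data") else np.asarray(vol_db)
    masks, tops, bottoms = [], [], []
    for b in range(data.shape[0]):
        wm = segment_bscan(data[b], params)
        masks.append(wm.mask)
        tops.append(wm.top_boundary)
        bottoms.append(wm.bottom_boundary)
    return WallMask(
        mask=np.stack(masks),
        top_boundary=np.stack(tops),
        bottom_boundary=np.stack(bottoms),
    )


def flatten_volume(
    vol_linear, wall: WallMask, crop_depth: int, background: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten every B-scan of a linear-intensity volume.

    Returns ``(flat, shifts)`` with ``flat[bscan, a_line, 0:crop_depth]``
    surface-aligned and ``shifts`` the per-(B-scan, A-line) top rows.
    """
    data = vol_linear.data if hasattr(vol_linear, "data") else np.asarray(vol_linear)
    nb = data.shape[0]
    flats = []
    for b in range(nb):
        wm = WallMask(
            mask=None if wall.mask is None else wall.mask[b],
            top_boundary=wall.top_boundary[b],
            bottom_boundary=wall.bottom_boundary[b],
        )
        flats.append(flatten(data[b], wm, crop_depth, background).image)
    return np.stack(flats), wall.top_boundary.copy()
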