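"""Translational registration of serial FIB-SEM cross sections.

Stage drift between milling cycles displaces consecutive faces by a few
pixels; it is overwhelmingly translational, so a translation-only model
is used (and keeps inversion exact for integer shifts).  Shifts are
estimated between consecutive sections by cross-correlation and
accumulated back to slice 0, which is robust to the slow morphological
change expected across ~90 nm of material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .io import VoxelGrid

__all__ = ["AlignmentResult", "estimate_shifts", "apply_shifts"]


@dataclass
class AlignmentResult:
    """Per-slice (dy, dx) shifts in px relative to slice 0, plus QC scores."""

    shifts: np.ndarray  # (nz, 2)
    residual: np.ndarray  # (nz,) correlation of slice (shift-corrected) with previous
    clipped: np.ndarray  # (nz,) bool, True where a pairwise shift hit max_shift_px

    def __post_init__(self) -> None:
        if not np.allclose(self.shifts[0], 0):
            raise ValueError("shift of slice 0 must be (0, 0) by convention")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def estimate_shifts(
    grid: VoxelGrid, subpixel: bool = False, max_shift_px: float = 20.0
) -> AlignmentResult:
    """Estimate per-slice translational drift relative to slice 0.

    Each consecutive pair is registered in two passes.  A fast
    FFT cross-correlation locates the peak; then an agreement mask is
    built from the residual image (the worst-disagreeing decile is
    dropped — this is where structure genuinely appears or vanishes
    between sections, e.g. the first section of an organelle or of the
    nucleus itself, which would otherwise bias the peak) and the shift
    is re-estimated by an explicit masked NCC scan around the first
    estimate, with quadratic sub-pixel interpolation when ``subpixel``.
    Pairwise shifts are accumulated to slice 0.  Shifts beyond
    ``max_shift_px`` are clamped and flagged; a zero-variance section
    contributes a (0, 0) pairwise shift with a flagged residual.
    """
    data = np.asarray(grid.data, dtype=np.float64)
    nz = data.shape[0]
    if nz < 2:
        raise ValueError("need at least 2 slices to register")
    pairwise = np.zeros((nz, 2))
    residual = np.ones(nz)
    clipped = np.zeros(nz, dtype=bool)
    for z in range(1, nz):
        ref, mov = data[z - 1], data[z]
        if ref.std() == 0 or mov.std() == 0:
            pairwise[z] = 0.0
            residual[z] = np.nan
            clipped[z] = True
            continue
        # difference-of-Gaussians band-pass: the lower scale suppresses
        # per-pixel shot noise, the upper scale removes slowly varying
        # intensity whose apparent lateral motion between sections would
        # bias the peak; what remains is the fine shared grain and the
        # membrane/organelle edges that actually carry the alignment
        ref_f = ndimage.gaussian_filter(ref, 1.0) - ndimage.gaussian_filter(ref, 6.0)
        mov_f = ndimage.gaussian_filter(mov, 1.0) - ndimage.gaussian_filter(mov, 6.0)
        coarse, _, _ = phase_cross_correlation(
            ref_f, mov_f, upsample_factor=20, normalization=None
        )
        correction, score = _masked_refine(ref_f, mov_f, np.round(coarse), subpixel)
        if not subpixel:
            correction = np.round(correction)
        elif np.all(np.round(coarse) == np.round(correction)):
            # the upsampled FFT fraction is more accurate than quadratic
            # interpolation; use it whenever both agree on the lattice cell
            correction = np.asarray(coarse, dtype=float)
        if np.any(np.abs(correction) > max_shift_px):
            correction = np.clip(correction, -max_shift_px, max_shift_px)
            clipped[z] = True
        if score < 0.05:
            # no registerable shared content between the two faces:
            # distrust the correlation peak rather than propagate it
            correction = np.zeros(2)
            clipped[z] = True
        # the correction registers this slice onto the previous one; the
        # drift displacement is its negation
        pairwise[z] = -correction
        residual[z] = score
    shifts = np.cumsum(pairwise, axis=0)
    return AlignmentResult(shifts=shifts, residual=residual, clipped=clipped)


def _int_shifted(img: np.ndarray, dy: int, dx: int) -> tuple[slice, slice, slice, slice]:
    """Slices (dst_y, dst_x, src_y, src_x) realising an integer translation."""
    h, w = img.shape
    src_y = slice(max(0, -dy), h - max(0, dy))
    src_x = slice(max(0, -dx), w - max(0, dx))
    dst_y = slice(max(0, dy), h - max(0, -dy))
    dst_x = slice(max(0, dx), w - max(0, -dx))
    return dst_y, dst_x, src_y, src_x


def _masked_ncc_surface(
    ref: np.ndarray, mov: np.ndarray, center: np.ndarray, mask: np.ndarray, radius: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """NCC over the agreement mask at integer offsets around ``center``."""
    offsets = np.arange(-radius, radius + 1)
    surface = np.full((len(offsets), len(offsets)), -np.inf)
    cy, cx = int(center[0]), int(center[1])
    for a, doy in enumerate(offsets):
        for b, dox in enumerate(offsets):
            dy, dx = cy + doy, cx + dox
            dst_y, dst_x, src_y, src_x = _int_shifted(mov, dy, dx)
            m = mask[dst_y, dst_x]
            if m.sum() < 100:
                continue
            surface[a, b] = _ncc(ref[dst_y, dst_x][m], mov[src_y, src_x][m])
    return surface, offsets


def _masked_refine(
    ref: np.ndarray, mov: np.ndarray, coarse: np.ndarray, subpixel: bool
) -> tuple[np.ndarray, float]:
    """Re-estimate the correction with disagreeing structure masked out."""
    cy, cx = int(coarse[0]), int(coarse[1])
    dst_y, dst_x, src_y, src_x = _int_shifted(mov, cy, cx)
    diff = np.full(ref.shape, np.inf)
    diff[dst_y, dst_x] = np.abs(ref[dst_y, dst_x] - mov[src_y, src_x])
    finite = np.isfinite(diff)
    cut = np.percentile(diff[finite], 90)
    mask = finite & (diff <= cut)
    surface, offsets = _masked_ncc_surface(ref, mov, coarse, mask)
    a, b = np.unravel_index(np.argmax(surface), surface.shape)
    best = np.array([cy + offsets[a], cx + offsets[b]], dtype=float)
    score = float(surface[a, b])
    if subpixel:
        for axis, idx in ((0, a), (1, b)):
            if not 0 < idx < surface.shape[axis] - 1:
                continue
            lo = surface[idx - 1, b] if axis == 0 else surface[a, idx - 1]
            hi = surface[idx + 1, b] if axis == 0 else surface[a, idx + 1]
            if np.isfinite(lo) and np.isfinite(hi):
                denom = lo - 2 * score + hi
                if denom < 0:
                    best[axis] += 0.5 * (lo - hi) / denom
    return best, score


def _shift_slice(img: np.ndarray, dy: float, dx: float, cval: float) -> np.ndarray:
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.full_like(img, cval)
        iy, ix = int(dy), int(dx)
        src_y = slice(max(0, -iy), img.shape[0] - max(0, iy))
        src_x = slice(max(0, -ix), img.shape[1] - max(0, ix))
        dst_y = slice(max(0, iy), img.shape[0] - max(0, -iy))
        dst_x = slice(max(0, ix), img.shape[1] - max(0, -ix))
        out[dst_y, dst_x] = img[src_y, src_x]
        return out
    return ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=cval)


def apply_shifts(grid: VoxelGrid, result: AlignmentResult | np.ndarray) -> VoxelGrid:
    """Undo the measured drift: translate slice z by minus its shift.

    ``result.shifts`` holds each slice's displacement relative to slice
    0 (the quantity ``estimate_shifts`` measures and the generator
    records), so alignment applies the negated shifts.  Integer shifts
    are exact roll-free translations with the vacated edge padded at the
    slice mean; fractional shifts use linear interpolation.  Output
    dimensions are unchanged.
    """
    shifts = result.shifts if isinstance(result, AlignmentResult) else np.asarray(result)
    data = np.asarray(grid.data, dtype=np.float64)
    if shifts.shape != (data.shape[0], 2):
        raise ValueError(
            f"need one (dy, dx) shift per slice: got {shifts.shape} for {data.shape[0]} slices"
        )
    out = np.empty_like(data)
    for z in range(data.shape[0]):
        # vacated margins are filled with the slice mean: a constant
        # fill at the background level keeps downstream intensity
        # statistics (thresholds, percentiles) unbiased, which a black
        # border would corrupt
        out[z] = _shift_slice(data[z], -shifts[z, 0], -shifts[z, 1], float(data[z].mean()))
    return VoxelGrid(out.astype(grid.data.dtype, copy=False), grid.spacing, grid.origin)
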