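"""Skin-thickness quantification from repeated structural volumes.

Pipeline order follows the study protocol: average the repeated scans,
trim edge frames and edge A-lines, track the top and bottom tissue
surfaces by intensity thresholding, exclude pigmented (low-backscatter)
A-lines, and convert the pixel separation to physical thickness with
``thickness_um = (bottom - top) * axial_pitch / tissue_index`` using a
skin refractive index of 1.376.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantom import ScanGeometry, StructuralVolume, from_db

__all__ = [
    "SurfacePair",
    "ThicknessResult",
    "average_repeats",
    "trim_stack",
    "detect_surfaces",
    "exclude_pigmented",
    "thickness_from_surfaces",
    "measure_thickness",
]


@dataclass
class SurfacePair:
    """Per-(frame, A-line) axial surface indices with a validity mask."""

    top_idx: np.ndarray  # (n_frames, n_alines) int
    bottom_idx: np.ndarray
    valid_mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        if self.top_idx.shape != self.bottom_idx.shape or self.top_idx.shape != self.valid_mask.shape:
            raise ValueError("surface arrays must share one shape")
        bad = self.valid_mask & (self.bottom_idx < self.top_idx)
        if np.any(bad):
            raise ValueError("bottom_idx < top_idx on valid A-lines")


@dataclass
class ThicknessResult:
    thickness_map_um: np.ndarray  # (n_frames, n_alines), NaN where invalid
    mean_um: float
    median_um: float
    n_alines_used: int
    excluded_fraction: float


def average_repeats(vol: StructuralVolume | np.ndarray) -> np.ndarray:
    """Arithmetic per-voxel mean over the repeat axis."""
    stacks = vol.stacks if isinstance(vol, StructuralVolume) else np.asarray(vol, float)
    if stacks.ndim != 4:
        raise ValueError("expected (n_repeats, n_frames, depth, n_alines)")
    return stacks.mean(axis=0)


def trim_stack(
    vol: np.ndarray, n_edge_frames: int = 100, n_edge_alines: int = 50
) -> np.ndarray:
    """Drop ``n_edge_frames`` frames from each end of the slow axis and
    ``n_edge_alines`` A-lines from each end of every B-scan.

    With the acquisition defaults (500 x 500) this retains 300 x 400
    A-lines per frame.  Works on (frames, depth, alines) or with a
    leading repeat axis.
    """
    if n_edge_frames < 0 or n_edge_alines < 0:
        raise ValueError("trim counts must be >= 0")
    arr = np.asarray(vol)
    fr_ax = arr.ndim - 3
    al_ax = arr.ndim - 1
    if arr.shape[fr_ax] <= 2 * n_edge_frames:
        raise ValueError("not enough frames to trim")
    if arr.shape[al_ax] <= 2 * n_edge_alines:
        raise ValueError("not enough A-lines to trim")
    sl = [slice(None)] * arr.ndim
    sl[fr_ax] = slice(n_edge_frames, arr.shape[fr_ax] - n_edge_frames)
    sl[al_ax] = slice(n_edge_alines, arr.shape[al_ax] - n_edge_alines)
    return arr[tuple(sl)]


def detect_surfaces(
    vol_db: np.ndarray,
    threshold_k: float = 4.0,
    n_background_rows: int = 20,
    axial_smooth_px: int = 3,
    median_window: int = 5,
) -> SurfacePair:
    """Track the top and bottom tissue surfaces by intensity thresholding.

    Per frame, the detection threshold is background mean plus
    ``threshold_k`` background SDs, estimated in linear intensity from
    the shallowest ``n_background_rows`` axial rows (assumed to be above
    the tissue).  Per A-line the top surface is the first axial index
    whose axially smoothed intensity exceeds the threshold and the
    bottom the last such index; both surfaces are then median-filtered
    laterally (window ``median_window``) for continuity.  A-lines with
    no supra-threshold sample are marked invalid; a frame with no valid
    A-line raises a warning and stays fully invalid.
    """
    arr = np.asarray(vol_db, float)
    if arr.ndim != 3:
        raise ValueError("expected an averaged (frames, depth, alines) volume")
    lin = from_db(arr)
    if axial_smooth_px > 1:
        lin = ndimage.uniform_filter1d(lin, size=axial_smooth_px, axis=1)
    n_frames, n_depth, n_alines = lin.shape
    bg = lin[:, :n_background_rows, :]
    thresh = bg.mean(axis=(1, 2)) + threshold_k * bg.std(axis=(1, 2))  # per frame

    above = lin > thresh[:, None, None]
    any_above = above.any(axis=1)
    top = above.argmax(axis=1)
    bottom = n_depth - 1 - above[:, ::-1, :].argmax(axis=1)

    for f in range(n_frames):
        if not any_above[f].any():
            warnings.warn(f"frame {f}: no surface found on any A-line; frame excluded")
            continue
        if median_window > 1:
            top[f] = ndimage.median_filter(top[f], size=median_window, mode="nearest")
            bottom[f] = ndimage.median_filter(bottom[f], size=median_window, mode="nearest")
    valid = any_above & (bottom >= top)
    return SurfacePair(top_idx=top, bottom_idx=bottom, valid_mask=valid)


def exclude_pigmented(
    vol_db: np.ndarray, surfaces: SurfacePair, percentile_cut: float = 5.0
) -> SurfacePair:
    """Invalidate A-lines whose mean in-tissue intensity is anomalously low.

    Pigment absorbs the probe light, so pigmented A-lines sit in the
    lower tail of the lateral distribution of mean in-tissue (linear)
    intensity; A-lines below the ``percentile_cut`` percentile of that
    distribution (computed over currently valid A-lines) are excluded.
    """
    if not 0.0 <= percentile_cut <= 100.0:
        raise ValueError("percentile_cut must be in [0, 100]")
    arr = np.asarray(vol_db, float)
    lin = from_db(arr)
    n_frames, n_depth, n_alines = lin.shape
    depth_idx = np.arange(n_depth)[None, :, None]
    in_tissue = (depth_idx >= surfaces.top_idx[:, None, :]) & (
        depth_idx <= surfaces.bottom_idx[:, None, :]
    )
    sums = np.where(in_tissue, lin, 0.0).sum(axis=1)
    counts = in_tissue.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_in_tissue = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    valid = surfaces.valid_mask & (counts > 0)
    if not valid.any():
        return replace(surfaces, valid_mask=valid)
    cut = np.percentile(mean_in_tissue[valid], percentile_cut)
    new_valid = valid & (mean_in_tissue >= cut)
    return SurfacePair(
        top_idx=surfaces.top_idx, bottom_idx=surfaces.bottom_idx, valid_mask=new_valid
    )


def thickness_from_surfaces(
    surfaces: SurfacePair,
    geometry: ScanGeometry | float,
    tissue_index: float = 1.376,
) -> ThicknessResult:
    """Convert surface pixel separations to physical thickness in um.

    ``geometry`` may be a :class:`ScanGeometry` or the axial pitch in um
    (optical path per pixel); physical thickness divides the optical
    path by the tissue refractive index.
    """
    pitch = geometry.axial_pitch_um if isinstance(geometry, ScanGeometry) else float(geometry)
    if not surfaces.valid_mask.any():
        raise ValueError("no valid A-lines to convert")
    thickness = (surfaces.bottom_idx - surfaces.top_idx) * pitch / tissue_index
    tmap = np.where(surfaces.valid_mask, thickness.astype(float), np.nan)
    used = tmap[surfaces.valid_mask]
    return ThicknessResult(
        thickness_map_um=tmap,
        mean_um=float(used.mean()),
        median_um=float(np.median(used)),
        n_alines_used=int(surfaces.valid_mask.sum()),
        excluded_fraction=float(1.0 - surfaces.valid_mask.mean()),
    )


def measure_thickness(
    vol: StructuralVolume,
    n_edge_frames: int = 100,
    n_edge_alines: int = 50,
    threshold_k: float = 4.0,
    percentile_cut: float = 5.0,
    **detect_kwargs,
) -> ThicknessResult:
    """Full pipeline: average -> trim -> detect -> exclude -> convert."""
    avg = average_repeats(vol)
    trimmed = trim_stack(avg, n_edge_frames=n_edge_frames, n_edge_alines=n_edge_alines)
    surfaces = detect_surfaces(trimmed, threshold_k=threshold_k, **detect_kwargs)
    surfaces = exclude_pigmented(trimmed, surfaces, percentile_cut=percentile_cut)
    return thickness_from_surfaces(surfaces, vol.geometry, vol.tissue_index)
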