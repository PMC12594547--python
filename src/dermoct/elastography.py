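"""Elastic-wave group velocity from phase-sensitive M-B-mode OCE data.

The wave launched at the field center propagates laterally in both
directions, so speed is estimated separately for the regions left and
right of the stimulation and the two sides averaged; a location's value
averages its longitudinal and transverse orientation means.

Displacement follows from the temporal phase derivative of the OCT
signal, ``u = dphi * lambda / (4 * pi * n)``; arrival delays between
lateral positions are measured by normalized cross-correlation with
parabolic sub-sample refinement, and the group velocity is the slope of
the distance-versus-delay regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .phantom import MBSeries

__all__ = [
    "SpaceTimeMap",
    "SideEstimate",
    "VelocityEstimate",
    "displacement_from_phase",
    "build_space_time",
    "estimate_side_velocity",
    "combine_velocities",
    "estimate_group_velocity",
]


@dataclass
class SpaceTimeMap:
    """Depth-aggregated displacement (nm), shape (n_positions, n_times)."""

    displacement: np.ndarray
    positions_um: np.ndarray
    times_s: np.ndarray
    excitation_x_um: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.positions_um) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")


@dataclass
class SideEstimate:
    side: str  # "left" | "right"
    speed_m_s: float
    r_squared: float
    n_positions: int
    valid: bool


@dataclass
class VelocityEstimate:
    v_left_m_s: float | None
    v_right_m_s: float | None
    v_mean_m_s: float
    fit_quality: dict
    frequency_hz: float | None = None
    n_pushes: int | None = None


def displacement_from_phase(mb: MBSeries) -> np.ndarray:
    """Unwrapped axial displacement in nm, shape (positions, times, depth).

    Consecutive temporal phase differences are wrapped back into
    (-pi, pi] (temporal unwrapping only) and cumulatively summed before
    conversion, so displacement at t=0 is zero by definition.
    """
    phase = np.asarray(mb.phase, float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase contains non-finite values")
    dphi = np.diff(phase, axis=1)
    dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
    cum = np.concatenate([np.zeros_like(phase[:, :1, :]), np.cumsum(dphi, axis=1)], axis=1)
    return cum * mb.wavelength_nm / (4.0 * np.pi * mb.tissue_index)


def build_space_time(
    displacement: np.ndarray,
    mb: MBSeries,
    top_idx: np.ndarray | int | None = None,
    window_px: int = 10,
    depth_window: tuple[int, int] | None = None,
) -> SpaceTimeMap:
    """Average displacement over a sub-surface depth window per (position, time).

    Either pass ``depth_window=(z0, z1)`` explicitly, or a tracked top
    surface (scalar or per-position array) from which a ``window_px``
    deep band is taken.  Wave energy is surface-weighted, so the default
    band starts at the top surface.
    """
    disp = np.asarray(displacement, float)
    n_pos, n_t, n_depth = disp.shape
    if depth_window is not None:
        z0, z1 = depth_window
        if z1 <= z0:
            raise ValueError("empty depth window")
        stm = disp[:, :, z0:z1].mean(axis=2)
    else:
        if top_idx is None:
            raise ValueError("need top_idx or depth_window")
        tops = np.broadcast_to(np.asarray(top_idx, int), (n_pos,))
        if window_px < 1:
            raise ValueError("empty depth window")
        stm = np.empty((n_pos, n_t))
        for i, z0 in enumerate(tops):
            z1 = min(int(z0) + window_px, n_depth)
            if z1 <= z0:
                raise ValueError("empty depth window")
            stm[i] = disp[i, :, int(z0):z1].mean(axis=1)
    return SpaceTimeMap(
        displacement=stm,
        positions_um=mb.positions_um,
        times_s=mb.times_s,
        excitation_x_um=mb.excitation_x_um,
    )


def _xcorr_delay(sig: np.ndarray, ref: np.ndarray) -> float:
    """Lag (samples, sub-sample) maximizing the cross-correlation of the
    mean-removed signals; positive when ``sig`` lags ``ref``."""
    a = sig - sig.mean()
    b = ref - ref.mean()
    c = np.correlate(a, b, mode="full")
    k = int(np.argmax(c))
    # parabolic refinement; ties broken toward the smaller delay by argmax
    if 0 < k < len(c) - 1:
        y0, y1, y2 = c[k - 1], c[k], c[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            k = k + 0.5 * (y0 - y2) / denom
    return float(k - (len(b) - 1))


def estimate_side_velocity(
    stm: SpaceTimeMap,
    side: str,
    min_offset_px: int = 3,
    r2_threshold: float = 0.8,
    max_positions: int | None = None,
) -> SideEstimate:
    """Time-of-flight group-velocity estimate for one side of the source.

    The reference is the first usable position at least ``min_offset_px``
    lateral pixels from the excitation center (near-field excluded);
    each farther position's arrival delay is the cross-correlation lag
    of its time profile against the reference, and speed is the slope of
    the least-squares distance-vs-delay fit.  The estimate is invalid
    (not an exception) when R^2 falls below ``r2_threshold``, when the
    slope is non-positive, or when the delays are degenerate.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    x = stm.positions_um
    pitch = float(np.median(np.diff(x)))
    offset_um = min_offset_px * pitch
    if side == "right":
        idx = np.where(x >= stm.excitation_x_um + offset_um)[0]
    else:
        idx = np.where(x <= stm.excitation_x_um - offset_um)[0][::-1]  # nearest first
    if max_positions is not None:
        idx = idx[:max_positions]
    if len(idx) < 5:
        return SideEstimate(side, float("nan"), 0.0, len(idx), False)
    ref = stm.displacement[idx[0]]
    dt = float(np.median(np.diff(stm.times_s)))
    dists = np.abs(x[idx] - x[idx[0]])  # um
    delays = np.array([_xcorr_delay(stm.displacement[i], ref) * dt for i in idx])
    if np.allclose(delays, 0.0):
        return SideEstimate(side, float("nan"), 0.0, len(idx), False)
    fit = sps.linregress(delays, dists)
    r2 = float(fit.rvalue**2)
    speed = float(fit.slope) * 1e-6  # um/s -> m/s
    valid = bool(np.isfinite(speed) and speed > 0 and r2 >= r2_threshold)
    return SideEstimate(side, speed, r2, len(idx), valid)


def combine_velocities(
    orientations: dict[str, tuple[SideEstimate, SideEstimate]],
    frequency_hz: float | None = None,
    n_pushes: int | None = None,
) -> VelocityEstimate:
    """Average valid sides within each orientation, then average orientations.

    ``orientations`` maps an orientation label (e.g. "longitudinal",
    "transverse") to its (left, right) side estimates.  Raises if no
    orientation has a valid side.
    """
    per_orientation = []
    quality = {}
    v_left = v_right = None
    for name, (left, right) in orientations.items():
        sides = [e for e in (left, right) if e.valid]
        quality[name] = {e.side: e.r_squared for e in (left, right)}
        if left.valid:
            v_left = left.speed_m_s
        if right.valid:
            v_right = right.speed_m_s
        if sides:
            per_orientation.append(float(np.mean([e.speed_m_s for e in sides])))
    if not per_orientation:
        raise ValueError("no valid side estimate in any orientation")
    return VelocityEstimate(
        v_left_m_s=v_left,
        v_right_m_s=v_right,
        v_mean_m_s=float(np.mean(per_orientation)),
        fit_quality=quality,
        frequency_hz=frequency_hz,
        n_pushes=n_pushes,
    )


def estimate_group_velocity(
    mb: MBSeries,
    top_idx: np.ndarray | int | None = None,
    window_px: int = 10,
    depth_window: tuple[int, int] | None = None,
    r2_threshold: float = 0.8,
    orientation: str = "longitudinal",
) -> VelocityEstimate:
    """Convenience pipeline for one M-B-mode dataset (one orientation)."""
    disp = displacement_from_phase(mb)
    if depth_window is None and top_idx is None:
        depth_window = (0, disp.shape[2])
    stm = build_space_time(
        disp, mb, top_idx=top_idx, window_px=window_px, depth_window=depth_window
    )
    left = estimate_side_velocity(stm, "left", r2_threshold=r2_threshold)
    right = estimate_side_velocity(stm, "right", r2_threshold=r2_threshold)
    return combine_velocities({orientation: (left, right)})
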