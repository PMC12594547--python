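"""Synthetic OCT / OCE / OCTA phantoms with known ground truth.

The generators emulate a swept-source OCT acquisition of layered skin:

* structural volumes carry fully developed speckle (circular complex
  Gaussian field, so pre-log intensity is exponentially distributed
  within a homogeneous layer) bounded by a top and bottom interface,
  with optional low-backscatter pigment patches;
* OCE records are M-B-mode phase series in which a windowed tone burst
  of known group velocity propagates laterally away from the field
  center, entering the phase as ``4*pi*n*u / lambda``;
* OCTA stacks are repeated B-scans where vessel-lumen voxels have a
  controllable fraction of their complex amplitude resampled between
  repeats while static tissue keeps one speckle realization;
* cohorts are long-format animal x group x site x day measurement
  tables with stated per-cell means/SDs and a shared per-animal random
  effect so paired comparisons are meaningful.

All randomness flows from the seed stored in the spec; identical spec
and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScanGeometry",
    "WaveSpec",
    "VesselSpec",
    "PigmentPatch",
    "PhantomSpec",
    "GroundTruth",
    "StructuralVolume",
    "MBSeries",
    "AngioStack",
    "CohortDesign",
    "generate_structural_volume",
    "generate_oce_dataset",
    "generate_octa_stack",
    "generate_cohort",
    "default_study_design",
]

_LOG_FLOOR = 1e-12  # linear intensity added before dB conversion


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry and timing of one OCT scan.

    Defaults mirror the study acquisition: 500 A-lines per B-scan,
    500 B-scans, 5 repeats over a 5.16 x 6.14 mm field at 1300 nm and a
    100 kHz A-line rate.  ``axial_pitch_um`` is optical path length per
    axial pixel.  ``n_depth`` (axial pixel count) defaults to 256.
    """

    n_alines: int = 500
    n_bscans: int = 500
    n_repeats: int = 5
    n_depth: int = 256
    axial_pitch_um: float = 5.0
    lateral_pitch_x_um: float = 5160.0 / 500
    lateral_pitch_y_um: float = 6140.0 / 500
    center_wavelength_nm: float = 1300.0
    aline_rate_hz: float = 100_000.0

    def __post_init__(self) -> None:
        for name in ("n_alines", "n_bscans", "n_repeats", "n_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "axial_pitch_um",
            "lateral_pitch_x_um",
            "lateral_pitch_y_um",
            "center_wavelength_nm",
            "aline_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.aline_rate_hz

    @property
    def field_x_um(self) -> float:
        return self.n_alines * self.lateral_pitch_x_um

    @property
    def field_y_um(self) -> float:
        return self.n_bscans * self.lateral_pitch_y_um


@dataclass(frozen=True)
class WaveSpec:
    """Laterally propagating displacement tone burst for OCE.

    ``n_pushes`` windowed sine cycles (1 = single push, 3 = push train)
    at ``frequency_hz`` travel away from ``excitation_x_um`` (``None``
    -> field center) at ``group_velocity_m_s``; amplitude decays as
    ``exp(-attenuation_per_mm * |x - x0| / 1000)`` and the displacement
    is exactly zero before the arrival time ``|x - x0| / c``.
    """

    frequency_hz: float = 5000.0
    n_pushes: int = 1
    group_velocity_m_s: float = 2.5
    amplitude_nm: float = 100.0
    attenuation_per_mm: float = 0.2
    excitation_x_um: float | None = None

    def __post_init__(self) -> None:
        if self.group_velocity_m_s <= 0:
            raise ValueError("group_velocity_m_s must be > 0")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be > 0")
        if self.n_pushes < 1:
            raise ValueError("n_pushes must be >= 1")
        if self.amplitude_nm < 0 or self.attenuation_per_mm < 0:
            raise ValueError("amplitude and attenuation must be >= 0")

    def displacement_nm(
        self, x_um: np.ndarray, t_s: np.ndarray, x0_um: float
    ) -> np.ndarray:
        """Causal displacement u(x, t) in nm; shape (len(x), len(t))."""
        dist_um = np.abs(np.asarray(x_um, float) - x0_um)[:, None]
        t = np.asarray(t_s, float)[None, :]
        arrival = dist_um * 1e-6 / self.group_velocity_m_s
        tau = t - arrival
        burst_len = self.n_pushes / self.frequency_hz
        window = (tau >= 0.0) & (tau <= burst_len)
        amp = self.amplitude_nm * np.exp(-self.attenuation_per_mm * dist_um / 1000.0)
        return np.where(window, amp * np.sin(2.0 * np.pi * self.frequency_hz * tau), 0.0)


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: a polyline centerline (physical um) with a circular lumen.

    ``centerline_um`` has rows (x, y, z): x along the A-line (fast) axis,
    y along the slow axis, z physical depth.  ``decorrelation`` is the
    fraction of complex amplitude independently resampled per repeat
    (1 = fully decorrelated flow).
    """

    centerline_um: tuple[tuple[float, float, float], ...]
    lumen_diameter_um: float
    decorrelation: float = 1.0

    def __post_init__(self) -> None:
        if self.lumen_diameter_um <= 0:
            raise ValueError("lumen_diameter_um must be > 0")
        if not 0.0 <= self.decorrelation <= 1.0:
            raise ValueError("decorrelation must be in [0, 1]")
        if len(self.centerline_um) < 2:
            raise ValueError("centerline needs >= 2 points")

    @staticmethod
    def along_slow_axis(
        x_um: float,
        z_um: float,
        geometry: ScanGeometry,
        lumen_diameter_um: float,
        decorrelation: float = 1.0,
    ) -> "VesselSpec":
        """Straight vessel spanning the slow axis at fixed (x, depth)."""
        return VesselSpec(
            centerline_um=((x_um, 0.0, z_um), (x_um, geometry.field_y_um, z_um)),
            lumen_diameter_um=lumen_diameter_um,
            decorrelation=decorrelation,
        )


@dataclass(frozen=True)
class PigmentPatch:
    """Lateral rectangle where backscatter is multiplied by ``attenuation``."""

    x0_um: float
    x1_um: float
    y0_um: float
    y1_um: float
    attenuation: float = 10 ** (-1.2)  # 12 dB

    def __post_init__(self) -> None:
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must be in (0, 1]")
        if self.x1_um <= self.x0_um or self.y1_um <= self.y0_um:
            raise ValueError("patch rectangle is degenerate")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic acquisition.

    ``top_surface_um`` / ``bottom_surface_um`` are physical interface
    depths, either scalars or (n_bscans, n_alines) maps.  Interface
    axial pixel = depth * tissue_index / axial_pitch (optical path).
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    top_surface_um: float | np.ndarray = 200.0
    bottom_surface_um: float | np.ndarray = 750.0
    tissue_index: float = 1.376
    layer_reflectivities: tuple[float, ...] = (1.0,)
    pigment_patches: tuple[PigmentPatch, ...] = ()
    wave: WaveSpec | None = None
    vessels: tuple[VesselSpec, ...] = ()
    phase_noise_rad: float = 0.05
    intensity_noise: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_index < 1.0:
            raise ValueError("tissue_index must be >= 1")
        if self.phase_noise_rad < 0 or self.intensity_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if any(r <= 0 for r in self.layer_reflectivities):
            raise ValueError("layer reflectivities must be > 0")
        top, bottom = self.surface_maps()
        if not np.all(bottom > top):
            raise ValueError("bottom_surface_um must exceed top_surface_um everywhere")
        g = self.geometry
        max_opl = g.n_depth * g.axial_pitch_um
        if np.any(bottom * self.tissue_index >= max_opl) or np.any(top < 0):
            raise ValueError("interfaces fall outside the axial range")

    def surface_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Interface depth maps broadcast to (n_bscans, n_alines), um."""
        g = self.geometry
        shape = (g.n_bscans, g.n_alines)
        top = np.broadcast_to(np.asarray(self.top_surface_um, float), shape)
        bottom = np.broadcast_to(np.asarray(self.bottom_surface_um, float), shape)
        return top, bottom

    def excitation_x_um(self) -> float:
        if self.wave is not None and self.wave.excitation_x_um is not None:
            return self.wave.excitation_x_um
        return self.geometry.field_x_um / 2.0


@dataclass
class GroundTruth:
    """Known truth attached to a generated dataset."""

    thickness_map_um: np.ndarray | None = None
    group_velocity_m_s: float | None = None
    vessel_mask: np.ndarray | None = None
    lumen_diameters_um: tuple[float, ...] = ()
    pigment_mask: np.ndarray | None = None
    top_surface_idx: np.ndarray | None = None
    bottom_surface_idx: np.ndarray | None = None
    seed: int = 0


@dataclass
class StructuralVolume:
    """Repeated structural stacks in dB; shape (n_repeats, n_bscans, depth, n_alines)."""

    stacks: np.ndarray
    geometry: ScanGeometry
    tissue_index: float = 1.376

    def __post_init__(self) -> None:
        g = self.geometry
        expected = (g.n_repeats, g.n_bscans, g.n_depth, g.n_alines)
        if self.stacks.shape != expected:
            raise ValueError(f"stacks shape {self.stacks.shape} != geometry {expected}")
        if not np.all(np.isfinite(self.stacks)):
            raise ValueError("stacks must be finite")


@dataclass
class MBSeries:
    """M-B-mode wrapped phase, shape (n_positions, n_times, depth).

    Positions advance along the lateral x axis at ``lateral_pitch_x_um``;
    time samples are spaced by 1/aline_rate.  Phase lies in (-pi, pi].
    """

    phase: np.ndarray
    geometry: ScanGeometry
    excitation_x_um: float
    tissue_index: float = 1.376
    wavelength_nm: float = 1300.0

    @property
    def positions_um(self) -> np.ndarray:
        return (np.arange(self.phase.shape[0]) + 0.5) * self.geometry.lateral_pitch_x_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.phase.shape[1]) * self.geometry.dt_s


@dataclass
class AngioStack:
    """Repeated B-scans (linear intensity), shape (n_repeats, n_bscans, depth, n_alines)."""

    repeats: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        if self.repeats.shape[0] < 2:
            raise ValueError("OCTA needs >= 2 repeats")


# ---------------------------------------------------------------------------
# internal field construction


def _reflectivity_volume(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Mean backscatter per voxel, (n_bscans, depth, n_alines), plus truth."""
    g = spec.geometry
    top, bottom = spec.surface_maps()
    z_opl = (np.arange(g.n_depth) + 0.5) * g.axial_pitch_um  # optical path, um
    z_phys = z_opl / spec.tissue_index
    # layer boundaries: tissue split equally among layer_reflectivities
    n_layers = len(spec.layer_reflectivities)
    refl = np.zeros((g.n_bscans, g.n_depth, g.n_alines))
    zp = z_phys[None, :, None]
    topb = top[:, None, :]
    botb = bottom[:, None, :]
    in_tissue = (zp >= topb) & (zp < botb)
    if n_layers == 1:
        refl = np.where(in_tissue, spec.layer_reflectivities[0], 0.0)
    else:
        frac = np.clip((zp - topb) / (botb - topb), 0.0, 1.0 - 1e-12)
        layer_idx = np.minimum((frac * n_layers).astype(int), n_layers - 1)
        layer_r = np.asarray(spec.layer_reflectivities)[layer_idx]
        refl = np.where(in_tissue, layer_r, 0.0)

    pigment_mask = np.zeros((g.n_bscans, g.n_alines), dtype=bool)
    if spec.pigment_patches:
        x_um = (np.arange(g.n_alines) + 0.5) * g.lateral_pitch_x_um
        y_um = (np.arange(g.n_bscans) + 0.5) * g.lateral_pitch_y_um
        for p in spec.pigment_patches:
            in_x = (x_um >= p.x0_um) & (x_um < p.x1_um)
            in_y = (y_um >= p.y0_um) & (y_um < p.y1_um)
            patch = np.outer(in_y, in_x)
            pigment_mask |= patch
            refl = np.where(patch[:, None, :], refl * p.attenuation, refl)

    top_idx = np.clip(
        np.round(top * spec.tissue_index / g.axial_pitch_um).astype(int), 0, g.n_depth - 1
    )
    bottom_idx = np.clip(
        np.round(bottom * spec.tissue_index / g.axial_pitch_um).astype(int),
        0,
        g.n_depth - 1,
    )
    truth = GroundTruth(
        thickness_map_um=bottom - top,
        pigment_mask=pigment_mask,
        top_surface_idx=top_idx,
        bottom_surface_idx=bottom_idx,
        seed=spec.seed,
    )
    return refl, truth


def _complex_speckle(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Circularly symmetric complex Gaussian with E[|E|^2] = 1."""
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)


def _to_db(intensity: np.ndarray) -> np.ndarray:
    return 10.0 * np.log10(intensity + _LOG_FLOOR)


def from_db(stacks_db: np.ndarray) -> np.ndarray:
    """Invert the dB scaling used by the generators."""
    return 10.0 ** (stacks_db / 10.0) - _LOG_FLOOR


# ---------------------------------------------------------------------------
# public generators


def generate_structural_volume(spec: PhantomSpec) -> tuple[StructuralVolume, GroundTruth]:
    """Repeated structural stacks with shared speckle, differing only by noise.

    Intensity per voxel is ``|E + n_r|**2`` with ``E`` the scatterer field
    (variance = layer reflectivity, shared across repeats) and ``n_r``
    per-repeat complex noise of variance ``intensity_noise``; stacks are
    returned in dB.
    """
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)
    refl, truth = _reflectivity_volume(spec)
    scatter = _complex_speckle(rng, refl.shape) * np.sqrt(refl)
    stacks = np.empty((g.n_repeats,) + refl.shape)
    for r in range(g.n_repeats):
        noise = (
            _complex_speckle(rng, refl.shape) * np.sqrt(spec.intensity_noise)
            if spec.intensity_noise > 0
            else 0.0
        )
        stacks[r] = _to_db(np.abs(scatter + noise) ** 2)
    return StructuralVolume(stacks=stacks, geometry=g, tissue_index=spec.tissue_index), truth


def generate_oce_dataset(spec: PhantomSpec) -> tuple[MBSeries, GroundTruth]:
    """M-B-mode phase series with a known-velocity wave launched at the center.

    One M-mode position per B-scan index (n_bscans positions), n_alines
    time samples per position.  The displacement enters the phase as
    ``4*pi*n*u / lambda`` added to a static speckle phase, wrapped to
    (-pi, pi], plus Gaussian phase noise.
    """
    if spec.wave is None:
        raise ValueError("spec.wave must be set for an OCE dataset")
    g = spec.geometry
    if spec.wave.frequency_hz > g.aline_rate_hz / 2.0:
        raise ValueError("excitation frequency exceeds the M-mode Nyquist rate")
    rng = np.random.default_rng(spec.seed)
    n_pos, n_t = g.n_bscans, g.n_alines
    x_um = (np.arange(n_pos) + 0.5) * g.lateral_pitch_x_um
    t_s = np.arange(n_t) * g.dt_s
    # default excitation: center of the M-mode position span
    if spec.wave.excitation_x_um is not None:
        x0 = spec.wave.excitation_x_um
    else:
        x0 = n_pos * g.lateral_pitch_x_um / 2.0
    u = spec.wave.displacement_nm(x_um, t_s, x0)  # (pos, time), nm

    top, bottom = spec.surface_maps()
    # one representative A-line of surfaces per position (center of fast axis)
    col = g.n_alines // 2
    top_pos = top[:n_pos, col] if top.shape[0] >= n_pos else np.full(n_pos, float(top.flat[0]))
    bot_pos = (
        bottom[:n_pos, col] if bottom.shape[0] >= n_pos else np.full(n_pos, float(bottom.flat[0]))
    )
    z_phys = ((np.arange(g.n_depth) + 0.5) * g.axial_pitch_um) / spec.tissue_index
    in_tissue = (z_phys[None, :] >= top_pos[:, None]) & (z_phys[None, :] < bot_pos[:, None])

    static = rng.uniform(-np.pi, np.pi, size=(n_pos, 1, g.n_depth))
    dphi = 4.0 * np.pi * spec.tissue_index * u / g.center_wavelength_nm  # (pos, time)
    phase = static + dphi[:, :, None] * in_tissue[:, None, :]
    if spec.phase_noise_rad > 0:
        phase = phase + rng.normal(0.0, spec.phase_noise_rad, size=phase.shape)
    phase = _wrap_phase(phase)

    top_idx = np.clip(
        np.round(top_pos * spec.tissue_index / g.axial_pitch_um).astype(int), 0, g.n_depth - 1
    )
    truth = GroundTruth(
        group_velocity_m_s=spec.wave.group_velocity_m_s,
        top_surface_idx=top_idx,
        seed=spec.seed,
    )
    mb = MBSeries(
        phase=phase,
        geometry=g,
        excitation_x_um=x0,
        tissue_index=spec.tissue_index,
        wavelength_nm=g.center_wavelength_nm,
    )
    return mb, truth


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    wrapped = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def _vessel_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean lumen mask, (n_bscans, depth, n_alines), from vessel polylines."""
    g = spec.geometry
    mask = np.zeros((g.n_bscans, g.n_depth, g.n_alines), dtype=bool)
    if not spec.vessels:
        return mask
    x_um = (np.arange(g.n_alines) + 0.5) * g.lateral_pitch_x_um
    y_um = (np.arange(g.n_bscans) + 0.5) * g.lateral_pitch_y_um
    z_um = ((np.arange(g.n_depth) + 0.5) * g.axial_pitch_um) / spec.tissue_index
    X = x_um[None, None, :]
    Y = y_um[:, None, None]
    Z = z_um[None, :, None]
    for v in spec.vessels:
        radius = v.lumen_diameter_um / 2.0
        pts = np.asarray(v.centerline_um, float)
        vmask = np.zeros_like(mask)
        for a, b in zip(pts[:-1], pts[1:]):
            d = b - a
            L2 = float(d @ d)
            if L2 == 0:
                continue
            t = ((X - a[0]) * d[0] + (Y - a[1]) * d[1] + (Z - a[2]) * d[2]) / L2
            t = np.clip(t, 0.0, 1.0)
            dx = X - (a[0] + t * d[0])
            dy = Y - (a[1] + t * d[1])
            dz = Z - (a[2] + t * d[2])
            vmask |= dx * dx + dy * dy + dz * dz <= radius * radius
        mask |= vmask
    return mask


def generate_octa_stack(spec: PhantomSpec) -> tuple[AngioStack, GroundTruth]:
    """Repeated B-scans where only vessel voxels decorrelate between repeats.

    Outside lumens every repeat shares one scatterer field; inside, a
    fraction ``decorrelation`` of the complex amplitude power is drawn
    independently per repeat, so inter-repeat intensity correlation
    falls with the decorrelation parameter.  Frames are linear intensity.
    """
    g = spec.geometry
    if g.n_repeats < 2:
        raise ValueError("OCTA needs >= 2 repeats")
    refl, truth = _reflectivity_volume(spec)
    lumen = _vessel_mask(spec)
    if spec.vessels:
        # every vessel must intersect the volume
        pts = np.concatenate([np.asarray(v.centerline_um, float) for v in spec.vessels])
        if (
            pts[:, 0].min() < 0
            or pts[:, 0].max() > g.field_x_um
            or pts[:, 2].min() < 0
            or pts[:, 2].max() * spec.tissue_index > g.n_depth * g.axial_pitch_um
        ):
            raise ValueError("vessel centerline outside the volume")
    rng = np.random.default_rng(spec.seed)
    amp = np.sqrt(np.where(lumen, np.maximum(refl, spec.layer_reflectivities[0]), refl))
    static = _complex_speckle(rng, refl.shape)

    # per-voxel decorrelation fraction
    dmap = np.zeros(refl.shape)
    for v in spec.vessels:
        single = replace(spec, vessels=(v,))
        dmap = np.maximum(dmap, _vessel_mask(single) * v.decorrelation)

    repeats = np.empty((g.n_repeats,) + refl.shape)
    keep = np.sqrt(1.0 - dmap)
    mix = np.sqrt(dmap)
    for r in range(g.n_repeats):
        fresh = _complex_speckle(rng, refl.shape)
        fld = amp * (keep * static + mix * fresh)
        if spec.intensity_noise > 0:
            fld = fld + _complex_speckle(rng, refl.shape) * np.sqrt(spec.intensity_noise)
        repeats[r] = np.abs(fld) ** 2
    truth.vessel_mask = lumen
    truth.lumen_diameters_um = tuple(v.lumen_diameter_um for v in spec.vessels)
    return AngioStack(repeats=repeats, geometry=g), truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortDesign:
    """Design of a longitudinal cohort.

    ``cell_means`` maps (group, metric, day) -> (mean, sd) in the
    metric's units; the same cell is used at every site.  Each animal
    carries a standard-normal random effect shared across its own
    records, weighted by ``sqrt(intra_animal_corr)`` so the marginal SD
    per cell equals the stated SD while repeated measures on one animal
    are positively correlated.
    """

    groups: tuple[str, ...]
    n_per_group: int
    days: tuple[int, ...]
    sites: tuple[str, ...]
    cell_means: dict
    intra_animal_corr: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0.0 <= self.intra_animal_corr < 1.0:
            raise ValueError("intra_animal_corr must be in [0, 1)")

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(sorted({k[1] for k in self.cell_means}))


def default_study_design(n_per_group: int = 15) -> CohortDesign:
    """Four-group bleomycin-fibrosis study layout (synthetic anchor values).

    Day-28 elastic-wave velocities for the fibrotic vs control contrast
    are anchored at 1.6 +/- 0.3 and 1.2 +/- 0.2 m/s; thickness and lumen
    trajectories are plausible synthetic values of matching magnitude.
    """
    groups = ("G1", "G2", "G3", "G4")
    days = (0, 7, 28)
    velocity = {
        "G1": {0: (1.15, 0.2), 7: (1.2, 0.2), 28: (1.2, 0.2)},
        "G2": {0: (1.15, 0.2), 7: (1.4, 0.25), 28: (1.6, 0.3)},
        "G3": {0: (1.15, 0.2), 7: (1.2, 0.2), 28: (1.2, 0.2)},
        "G4": {0: (1.15, 0.2), 7: (1.3, 0.25), 28: (1.35, 0.25)},
    }
    thickness = {
        "G1": {0: (600.0, 60.0), 7: (610.0, 60.0), 28: (620.0, 60.0)},
        "G2": {0: (600.0, 60.0), 7: (800.0, 80.0), 28: (1000.0, 100.0)},
        "G3": {0: (600.0, 60.0), 7: (610.0, 60.0), 28: (620.0, 60.0)},
        "G4": {0: (600.0, 60.0), 7: (760.0, 80.0), 28: (960.0, 100.0)},
    }
    lumen = {
        "G1": {0: (40.0, 6.0), 7: (40.5, 6.0), 28: (41.0, 6.0)},
        "G2": {0: (40.0, 6.0), 7: (45.0, 7.0), 28: (48.0, 8.0)},
        "G3": {0: (40.0, 6.0), 7: (40.5, 6.0), 28: (41.0, 6.0)},
        "G4": {0: (40.0, 6.0), 7: (44.0, 7.0), 28: (46.5, 8.0)},
    }
    cells = {}
    for g in groups:
        for d in days:
            cells[(g, "velocity_m_s", d)] = velocity[g][d]
            cells[(g, "thickness_um", d)] = thickness[g][d]
            cells[(g, "lumen_um", d)] = lumen[g][d]
    return CohortDesign(
        groups=groups,
        n_per_group=n_per_group,
        days=days,
        sites=("top", "bottom"),
        cell_means=cells,
    )


def generate_cohort(design: CohortDesign, seed: int = 0) -> pd.DataFrame:
    """Long-format records (animal_id, group, site, day, metric, value)."""
    rng = np.random.default_rng(seed)
    rho = design.intra_animal_corr
    rows = []
    for g in design.groups:
        for i in range(design.n_per_group):
            animal = f"{g}-a{i:02d}"
            b = rng.standard_normal()  # shared per-animal effect
            for metric in design.metrics:
                for day in design.days:
                    mean, sd = design.cell_means[(g, metric, day)]
                    for site in design.sites:
                        e = rng.standard_normal()
                        value = mean + sd * (np.sqrt(rho) * b + np.sqrt(1.0 - rho) * e)
                        rows.append((animal, g, site, day, metric, value))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "site", "day", "metric", "value"]
    )
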