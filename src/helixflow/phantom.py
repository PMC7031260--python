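"""Analytic synthetic 4D flow phantoms with machine-readable ground truth.

The phantom is a straight rigid tube (axis z) carrying Poiseuille axial
flow with an optional temporal waveform, plus an optional Rankine swirl of
known handedness that can be gated to a phase window and confined to an
axial band — an idealisation of the corkscrew-like helical flow seen in
the ascending aorta.  The Rankine vortex is chosen over smoother profiles
because its radial pressure deficit has a piecewise closed form, giving an
exact oracle for the pressure solver:

    dp(r) = -rho*W^2*rc^2 + rho*W^2*r^2/2      for r <= rc
    dp(r) = -rho*W^2*rc^4 / (2 r^2)            for r  > rc

(relative to the far field; W = angular rate, rc = core radius).

Defaults mirror a typical aortic 4D flow acquisition: 25 cardiac phases,
dt 40 ms over a 1000 ms cycle, 2 mm isotropic voxels, velocities below a
150 cm/s Venc.  Everything is deterministic given the seed.

Known, deliberate limitation: a steady Poiseuille phantom *without* swirl
produces a viscous axial pressure ramp whose downstream half is P < 0
after mean subtraction — a false-positive helix.  The gated-helix recovery
phantom therefore carries no mean axial flow, and the tests pin the
false-positive mode explicitly rather than hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional

import numpy as np

from .centerline import Centerline
from .errors import DomainError
from .fields import MMHG_PA, SegmentationMask, VelocityField4D

__all__ = ["SwirlSpec", "PhantomSpec", "GroundTruth", "make_tube_phantom",
           "add_swirl", "analytic_rankine_pressure", "add_noise",
           "ground_truth_helix_mask", "preset_poiseuille",
           "preset_rankine_steady", "preset_gated_helix"]


@dataclass
class SwirlSpec:
    """Rankine swirl: solid-body core, irrotational exterior.

    ``sign=+1`` is counter-clockwise about +z in stored coordinates, which
    the cross-section chart of the rotation-direction algorithm reports as
    RD− (see :mod:`helixflow.rotation`).  The gate [phase_on, phase_off)
    and axial band [z_min_mm, z_max_mm) bound the swirl in time and space.
    """

    r_core_mm: float = 5.0
    omega_rad_s: float = 100.0
    sign: int = 1
    phase_on: int = 0
    phase_off: Optional[int] = None    # exclusive; None -> all phases
    z_min_mm: Optional[float] = None   # None -> full length
    z_max_mm: Optional[float] = None


@dataclass
class PhantomSpec:
    radius_mm: float = 10.0
    length_mm: float = 120.0
    spacing_mm: float = 2.0
    n_phases: int = 25
    dt_ms: float = 40.0
    cycle_length_ms: float = 1000.0
    v_mean: float = 0.2                # cycle-mean axial speed, m/s
    waveform: str = "steady"           # "steady" | "pulse"
    systole_ms: float = 300.0          # raised-cosine pulse duration
    swirl: Optional[SwirlSpec] = None
    noise_sigma: float = 0.0           # m/s
    seed: int = 0
    margin_voxels: int = 2

    def validate(self) -> "PhantomSpec":
        if self.radius_mm <= 0 or self.length_mm <= 0 or self.spacing_mm <= 0:
            raise DomainError("tube geometry must be positive")
        if self.n_phases < 2:
            raise DomainError("need at least 2 phases")
        if self.waveform not in ("steady", "pulse"):
            raise DomainError("waveform must be 'steady' or 'pulse'")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if self.swirl is not None and self.swirl.r_core_mm >= self.radius_mm:
            raise DomainError("swirl core radius must be smaller than the tube radius")
        return self


@dataclass
class GroundTruth:
    """Analytic expectations for the generated phantom."""

    swirl_phases: list
    th_ex_abs_ms: float
    th_ex_rel_pct: float
    band_length_mm: Optional[float]
    swirl_sign: Optional[int]
    expected_rd_label: Optional[str]
    net_flow_ml_per_cycle: float
    peak_velocity_m_s: float
    core_pressure_deficit_mmhg: Optional[float]
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _waveform(spec: PhantomSpec) -> np.ndarray:
    """Per-phase axial scaling w(t); normalized so the cycle mean is 1
    (net flow per cycle is pi*R^2*v_mean regardless of waveform)."""
    t = np.arange(spec.n_phases) * spec.dt_ms
    if spec.waveform == "steady":
        return np.ones(spec.n_phases)
    w = np.where(t < spec.systole_ms,
                 0.5 * (1 - np.cos(2 * np.pi * t / spec.systole_ms)), 0.0)
    mean = w.mean()
    if mean <= 0:
        raise DomainError("degenerate waveform: zero mean")
    return w / mean


def _grid(spec: PhantomSpec):
    h = spec.spacing_mm
    half = spec.radius_mm + spec.margin_voxels * h
    n_xy = 2 * int(np.ceil(half / h)) + 1
    nz = int(round(spec.length_mm / h)) + 1
    cx = (n_xy - 1) // 2
    origin = np.array([-cx * h, -cx * h, 0.0])
    x = (np.arange(n_xy) - cx) * h
    z = np.arange(nz) * h
    X, Y = np.meshgrid(x, x, indexing="ij")
    return origin, X, Y, z, n_xy, nz


def make_tube_phantom(spec: PhantomSpec):
    """Build the tube phantom.

    Returns ``(VelocityField4D, SegmentationMask, Centerline, GroundTruth)``.
    Axial velocity is the Poiseuille profile ``2*v_mean*(1 - r^2/R^2)``
    scaled by the waveform; the mask is ``r <= R``; the centerline is the
    tube axis.  Swirl and noise are applied per the spec.  Two calls with
    the same spec (and seed) produce bit-identical fields.
    """
    spec.validate()
    origin, X, Y, z, n_xy, nz = _grid(spec)
    h = spec.spacing_mm
    r2 = X**2 + Y**2
    disc = r2 <= spec.radius_mm**2 + 1e-9
    mask_vox = np.repeat(disc[:, :, None], nz, axis=2)

    w = _waveform(spec)
    profile = np.where(disc, 2.0 * spec.v_mean * (1.0 - r2 / spec.radius_mm**2), 0.0)
    values = np.zeros((3, n_xy, n_xy, nz, spec.n_phases))
    values[2] = profile[:, :, None, None] * w[None, None, None, :]

    field = VelocityField4D(values, np.full(3, h), spec.dt_ms,
                            spec.cycle_length_ms, origin, venc=150.0)
    mask = SegmentationMask(mask_vox, np.full(3, h), origin.copy())
    cl = Centerline.from_points(
        np.column_stack([np.zeros(nz), np.zeros(nz), z]), sampling_step=1.0
    )

    swirl_phases: list = []
    band_len = None
    deficit = None
    sign = None
    rd_label = None
    if spec.swirl is not None:
        field = add_swirl(field, spec)
        sw = spec.swirl
        off = sw.phase_off if sw.phase_off is not None else spec.n_phases
        swirl_phases = list(range(sw.phase_on, off))
        z0 = sw.z_min_mm if sw.z_min_mm is not None else 0.0
        z1 = sw.z_max_mm if sw.z_max_mm is not None else spec.length_mm
        band_len = z1 - z0
        deficit = analytic_rankine_pressure(0.0, sw.omega_rad_s, sw.r_core_mm)
        sign = sw.sign
        # straight +z tangent: the (nx, ny, n) chart is left-handed, so a
        # counter-clockwise (+1) swirl about +z classifies as RD-
        rd_label = "RD-" if sign > 0 else "RD+"
    if spec.noise_sigma > 0:
        field = add_noise(field, spec.noise_sigma, spec.seed)

    th_abs = spec.dt_ms * len(swirl_phases)
    gt = GroundTruth(
        swirl_phases=swirl_phases,
        th_ex_abs_ms=th_abs,
        th_ex_rel_pct=100.0 * th_abs / spec.cycle_length_ms,
        band_length_mm=band_len,
        swirl_sign=sign,
        expected_rd_label=rd_label,
        net_flow_ml_per_cycle=np.pi * spec.radius_mm**2 * spec.v_mean
        * spec.cycle_length_ms / 1000.0,
        peak_velocity_m_s=2.0 * spec.v_mean * float(_waveform(spec).max()),
        core_pressure_deficit_mmhg=deficit,
        seed=spec.seed,
    )
    return field, mask, cl, gt


def add_swirl(field: VelocityField4D, spec: PhantomSpec) -> VelocityField4D:
    """Superimpose the Rankine azimuthal velocity within the phase gate and
    axial band: v_theta = W r in the core, W rc^2 / r outside, up to the
    tube wall.  Returns a new field."""
    sw = spec.swirl
    if sw is None:
        return field.copy()
    if sw.r_core_mm <= 0 or sw.omega_rad_s < 0 or sw.sign not in (-1, 1):
        raise DomainError("invalid swirl parameters")
    out = field.copy()
    origin, X, Y, z, n_xy, nz = _grid(spec)
    r = np.sqrt(X**2 + Y**2)
    rc = sw.r_core_mm
    # velocities in m/s need radii in m; omega in rad/s
    r_m = r * 1e-3
    rc_m = rc * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        v_theta = np.where(r <= rc, sw.omega_rad_s * r_m,
                           sw.omega_rad_s * rc_m**2 / np.where(r_m > 0, r_m, np.inf))
    v_theta = np.where(r <= spec.radius_mm + 1e-9, v_theta, 0.0)
    with np.errstate(invalid="ignore"):
        ux = np.where(r > 0, -Y / r, 0.0) * v_theta * sw.sign
        uy = np.where(r > 0, X / r, 0.0) * v_theta * sw.sign

    z0 = sw.z_min_mm if sw.z_min_mm is not None else -np.inf
    z1 = sw.z_max_mm if sw.z_max_mm is not None else np.inf
    in_band = (z >= z0) & (z < z1)
    off = sw.phase_off if sw.phase_off is not None else spec.n_phases
    zi = np.flatnonzero(in_band)
    for t in range(sw.phase_on, off):
        # advanced indexing puts the z-selection axis first: shape (nz, nx, ny)
        out.values[0, :, :, zi, t] = out.values[0, :, :, zi, t] + ux[None, :, :]
        out.values[1, :, :, zi, t] = out.values[1, :, :, zi, t] + uy[None, :, :]
    return out


def analytic_rankine_pressure(r_mm, omega_rad_s: float = 100.0,
                              r_core_mm: float = 5.0,
                              rho: float = 1060.0):
    """Closed-form Rankine radial pressure (mmHg) relative to the far field."""
    r = np.asarray(r_mm, dtype=float) * 1e-3
    rc = r_core_mm * 1e-3
    w2 = omega_rad_s**2
    with np.errstate(divide="ignore"):
        outer = -rho * w2 * rc**4 / (2.0 * np.where(r > 0, r, np.inf) ** 2)
    inner = -rho * w2 * rc**2 + rho * w2 * r**2 / 2.0
    dp_pa = np.where(r <= rc, inner, outer)
    return dp_pa / MMHG_PA


def add_noise(field: VelocityField4D, sigma: float, seed: int) -> VelocityField4D:
    """Add i.i.d. Gaussian velocity noise (m/s) per component/voxel/phase;
    deterministic for a given seed."""
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    out = field.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        out.values += rng.normal(0.0, sigma, size=out.values.shape)
    return out


def ground_truth_helix_mask(spec: PhantomSpec):
    """Analytic helix mask of the swirl phantom: the vortex core
    (r <= r_core) within the axial band during the gated phases.

    This is the generator's ground truth, independent of the pressure
    pipeline; it backs the phase-counting/volume/length recovery tests.
    Returns a :class:`helixflow.pressure.HelixMask`.
    """
    from .pressure import HelixMask  # local import to avoid a cycle

    spec.validate()
    if spec.swirl is None:
        raise DomainError("ground-truth helix mask requires a swirl")
    sw = spec.swirl
    origin, X, Y, z, n_xy, nz = _grid(spec)
    core = (X**2 + Y**2) <= sw.r_core_mm**2 + 1e-9
    z0 = sw.z_min_mm if sw.z_min_mm is not None else -np.inf
    z1 = sw.z_max_mm if sw.z_max_mm is not None else np.inf
    in_band = (z >= z0) & (z < z1)
    region = core[:, :, None] & in_band[None, None, :]
    vox = np.zeros((n_xy, n_xy, nz, spec.n_phases), dtype=bool)
    off = sw.phase_off if sw.phase_off is not None else spec.n_phases
    vox[..., sw.phase_on:off] = region[..., None]
    return HelixMask(voxels=vox, spacing=np.full(3, spec.spacing_mm),
                     origin=origin)


def preset_poiseuille(v_mean: float = 0.2, waveform: str = "steady",
                      seed: int = 0) -> PhantomSpec:
    """Plain Poiseuille tube (flow-quantification oracle)."""
    return PhantomSpec(v_mean=v_mean, waveform=waveform, seed=seed)


def preset_rankine_steady(omega_rad_s: float = 100.0, r_core_mm: float = 5.0,
                          sign: int = 1, spacing_mm: float = 2.0,
                          n_phases: int = 3, seed: int = 0) -> PhantomSpec:
    """Steady full-length Rankine swirl, no axial flow (pressure oracle).

    A few identical phases suffice: the field is time-invariant.
    """
    dt = 40.0
    return PhantomSpec(
        spacing_mm=spacing_mm, n_phases=n_phases, dt_ms=dt,
        cycle_length_ms=max(1000.0, n_phases * dt), v_mean=0.0,
        swirl=SwirlSpec(r_core_mm=r_core_mm, omega_rad_s=omega_rad_s,
                        sign=sign),
        seed=seed,
    )


def preset_gated_helix(sign: int = 1, seed: int = 0) -> PhantomSpec:
    """Gated helix recovery phantom: Rankine swirl on phases 5–14 of 25,
    confined to the axial band [40, 80) mm of the 120 mm tube; no mean
    axial flow (the axial pressure ramp of Poiseuille flow is a documented
    false-positive mode that would contaminate the temporal recovery)."""
    return PhantomSpec(
        v_mean=0.0,
        swirl=SwirlSpec(r_core_mm=5.0, omega_rad_s=100.0, sign=sign,
                        phase_on=5, phase_off=15, z_min_mm=40.0, z_max_mm=80.0),
        seed=seed,
    )
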