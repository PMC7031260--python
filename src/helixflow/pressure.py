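"""Relative pressure mapping from 4D velocity fields.

The pressure gradient is estimated from the Navier–Stokes momentum balance

    G = -rho * (dv/dt + (v . grad) v) + mu * laplacian(v)

with central differences inside the segmentation (one-sided at the mask
boundary) and a cyclic temporal derivative over the cardiac cycle.  The
relative pressure is then recovered per phase by an iterative relaxation:
each voxel repeatedly becomes the mean of its face-neighbors' pressures
plus the midpoint-gradient increment along the connecting edge.  The
solution is gauge-free; each phase is anchored to zero mean over the mask.

Post-processing follows the published recipe: one pass of a separable
3x3x3 binomial filter (mask-aware), winsorisation to the 1–99% quantile
range, and subtraction of the mean of the filtered values so the map stays
relative to the average pressure.  Voxels with P < 0 mmHg form the helix
mask used by the downstream helix metrics and pathline filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DomainError, StructuralError
from .fields import MMHG_PA, SegmentationMask, VelocityField4D

__all__ = [
    "PressureSolverConfig", "PressureMap", "HelixMask",
    "pressure_gradient", "solve_relative_pressure", "postprocess_pressure",
    "helix_mask", "compute_pressure_map",
]


@dataclass
class PressureSolverConfig:
    """Physical constants and relaxation controls.

    rho/mu default to standard blood values (1060 kg/m^3, 4 mPa*s);
    tolerance is the largest per-voxel pressure update (mmHg) accepted as
    converged.
    """

    rho: float = 1060.0
    mu: float = 0.004
    tolerance: float = 1e-6
    max_iterations: int = 5000
    omega: float = 0.8   # Jacobi damping; 1.0 = undamped

    def __post_init__(self):
        if self.rho <= 0 or self.mu < 0:
            raise DomainError("rho must be positive, mu non-negative")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise DomainError("invalid tolerance / max_iterations")
        if not (0 < self.omega <= 1):
            raise DomainError("omega must be in (0, 1]")


@dataclass
class PressureMap:
    """Per-voxel, per-phase relative pressure (mmHg) within the mask.

    ``values`` has shape (nx, ny, nz, n_phases) and is zero outside the
    mask.  ``clamp_bounds`` / ``mean_shift`` are populated by
    :func:`postprocess_pressure`.
    """

    values: np.ndarray
    mask: SegmentationMask
    converged: np.ndarray
    iterations: np.ndarray
    clamp_bounds: Optional[tuple] = None
    mean_shift: Optional[np.ndarray] = None
    shift_scope: str = "none"

    @property
    def n_phases(self) -> int:
        return self.values.shape[-1]

    def masked_values(self) -> np.ndarray:
        """All in-mask samples, shape (n_mask_voxels, n_phases)."""
        return self.values[self.mask.voxels]


@dataclass
class HelixMask:
    """Binary P < 0 indicator per voxel and phase (subset of the mask)."""

    voxels: np.ndarray          # boolean (nx, ny, nz, n_phases)
    spacing: np.ndarray
    origin: np.ndarray

    @property
    def n_phases(self) -> int:
        return self.voxels.shape[-1]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _shifted(a: np.ndarray, axis: int, step: int) -> np.ndarray:
    """out[i] = a[i + step] along ``axis``; vacated edge filled with 0."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step == 1:
        src[axis], dst[axis] = slice(1, None), slice(None, -1)
    elif step == -1:
        src[axis], dst[axis] = slice(None, -1), slice(1, None)
    else:
        raise ValueError("step must be +/-1")
    out[tuple(dst)] = a[tuple(src)]
    return out


def _masked_derivative(a: np.ndarray, mask: np.ndarray, axis: int, h: float) -> np.ndarray:
    """First derivative of ``a`` along ``axis`` restricted to ``mask``:
    central where both neighbors are in-mask, one-sided at the boundary,
    zero where the voxel has no in-mask neighbor along the axis."""
    m = mask.astype(float)
    has_p = _shifted(m, axis, +1) > 0
    has_m = _shifted(m, axis, -1) > 0
    a_p = _shifted(a, axis, +1)
    a_m = _shifted(a, axis, -1)
    d = np.zeros_like(a)
    both = has_p & has_m
    d[both] = (a_p[both] - a_m[both]) / (2 * h)
    only_p = has_p & ~has_m
    d[only_p] = (a_p[only_p] - a[only_p]) / h
    only_m = has_m & ~has_p
    d[only_m] = (a[only_m] - a_m[only_m]) / h
    d[~mask] = 0.0
    return d


def _masked_laplacian(a: np.ndarray, mask: np.ndarray, hs) -> np.ndarray:
    """Sum over axes of (a_neighbor - a)/h^2 over in-mask face neighbors
    (homogeneous-Neumann behavior at the mask boundary)."""
    lap = np.zeros_like(a)
    m = mask.astype(float)
    for axis, h in enumerate(hs):
        for step in (+1, -1):
            valid = (_shifted(m, axis, step) > 0) & mask
            nb = _shifted(a, axis, step)
            lap[valid] += (nb[valid] - a[valid]) / h**2
    return lap


def _check_not_degenerate(mask: np.ndarray):
    for axis in range(3):
        if np.any(mask & (_shifted(mask.astype(float), axis, 1) > 0)):
            return
    raise DomainError("mask is thinner than the difference stencil everywhere")


def pressure_gradient(fld: VelocityField4D, mask: SegmentationMask,
                      cfg: PressureSolverConfig | None = None) -> np.ndarray:
    """Navier–Stokes pressure-gradient estimate, shape (3, nx, ny, nz, n_phases).

    Units mmHg/mm; zero outside the mask.  The temporal derivative is the
    cyclic central difference over the cardiac cycle.
    """
    cfg = cfg or PressureSolverConfig()
    mask.check_congruent(fld)
    mvox = mask.voxels
    _check_not_degenerate(mvox)

    v = fld.values  # (3, nx, ny, nz, nt), m/s
    nt = fld.n_phases
    h_m = fld.spacing * 1e-3  # m
    dt_s = fld.dt * 1e-3      # s

    # cyclic temporal derivative
    dvdt = (np.roll(v, -1, axis=-1) - np.roll(v, 1, axis=-1)) / (2 * dt_s)

    G = np.zeros_like(v)
    for t in range(nt):
        vt = v[..., t]
        # spatial derivatives of each component along each axis
        dv = np.empty((3, 3) + fld.shape)  # dv[c, a] = d v_c / d x_a
        for c in range(3):
            for a in range(3):
                dv[c, a] = _masked_derivative(vt[c], mvox, a, h_m[a])
        conv = np.einsum("axyz,caxyz->cxyz", vt, dv)
        lap = np.stack([_masked_laplacian(vt[c], mvox, h_m) for c in range(3)])
        G[..., t] = -cfg.rho * (dvdt[..., t] + conv) + cfg.mu * lap

    G /= MMHG_PA * 1000.0  # Pa/m -> mmHg/mm
    G[:, ~mvox] = 0.0
    return G


def solve_relative_pressure(gradient: np.ndarray, mask: SegmentationMask,
                            cfg: PressureSolverConfig | None = None) -> PressureMap:
    """Integrate the gradient into a per-phase relative pressure map by
    Jacobi relaxation over the face-neighbor graph of the mask.

    Each sweep sets every voxel to the mean over its in-mask face-neighbors
    of ``p_neighbor + G_mid . (x_voxel - x_neighbor)`` with the midpoint
    gradient on the connecting edge; iteration stops when the largest
    update falls below ``cfg.tolerance`` (mmHg) or at the iteration cap
    (recorded in the ``converged`` flags, not fatal).  Each phase is
    anchored to zero mean over the mask.

    The sweep is under-relaxed (``cfg.omega``, default 0.8): plain Jacobi
    leaves its highest-frequency (checkerboard) mode undamped, which on a
    gradient field with a non-conservative residual sustains a limit-cycle
    oscillation instead of converging; damping restores convergence without
    changing the fixed point.
    """
    cfg = cfg or PressureSolverConfig()
    if gradient.ndim != 5 or gradient.shape[0] != 3:
        raise StructuralError(f"gradient must be (3, nx, ny, nz, nt); got {gradient.shape}")
    if gradient.shape[1:4] != tuple(mask.shape):
        raise StructuralError("gradient grid does not match mask grid")
    if not np.all(np.isfinite(gradient[:, mask.voxels])):
        raise DomainError("gradient is not finite on the mask")
    mvox = mask.voxels
    nt = gradient.shape[-1]
    h = mask.spacing  # mm

    # precompute neighbor validity per axis/direction (as floats: the sweep
    # is pure array arithmetic, no fancy indexing in the hot loop)
    m = mvox.astype(float)
    valid = {}
    for a in range(3):
        for s in (+1, -1):
            valid[(a, s)] = ((_shifted(m, a, s) > 0) & mvox).astype(float)
    den = np.zeros(mask.shape)
    for va in valid.values():
        den += va
    isolated = mvox & (den == 0)
    den_safe = np.where(den > 0, den, 1.0)
    w = cfg.omega

    values = np.zeros(mask.shape + (nt,))
    converged = np.zeros(nt, dtype=bool)
    iterations = np.zeros(nt, dtype=int)
    for t in range(nt):
        G = gradient[..., t]
        # constant part of the update: mean over neighbors of the edge increments
        const = np.zeros(mask.shape)
        for a in range(3):
            for s in (+1, -1):
                # x_i - x_j = -s*h along axis a
                const += valid[(a, s)] * ((-s) * h[a] * 0.5
                                          * (G[a] + _shifted(G[a], a, s)))
        const /= den_safe

        # initial guess: midpoint-rule cumulative integration of the
        # gradient along the longest grid axis.  Long-wavelength axial
        # modes are Jacobi's slowest; seeding them from the line integral
        # leaves the relaxation only short-range corrections.  The fixed
        # point is unchanged.
        p = np.zeros(mask.shape)
        ax = int(np.argmax(mask.shape))
        Ga = np.moveaxis(G[ax], ax, 0)
        pa = np.moveaxis(p, ax, 0)
        for k in range(1, mask.shape[ax]):
            pa[k] = pa[k - 1] + h[ax] * 0.5 * (Ga[k - 1] + Ga[k])
        p[~mvox] = 0.0
        for it in range(1, cfg.max_iterations + 1):
            num = np.zeros(mask.shape)
            for a in range(3):
                for s in (+1, -1):
                    num += valid[(a, s)] * _shifted(p, a, s)
            p_new = (1 - w) * p + w * (num / den_safe + const)
            p_new[isolated] = p[isolated]
            p_new[~mvox] = 0.0
            delta = float(np.max(np.abs(p_new - p)[mvox]))
            p = p_new
            if delta < cfg.tolerance:
                converged[t] = True
                break
        iterations[t] = it
        p[mvox] -= p[mvox].mean()   # Neumann gauge: zero mean per phase
        p[~mvox] = 0.0
        values[..., t] = p
    return PressureMap(values=values, mask=mask, converged=converged,
                       iterations=iterations)


def _binomial_smooth_phase(p: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """One pass of the separable (1,2,1)/4 kernel per axis, with weights
    renormalized over in-mask neighbors so constants are preserved."""
    w = np.array([0.25, 0.5, 0.25])
    num = p * mask
    den = mask.astype(float)
    for axis in range(3):
        num = ndimage.correlate1d(num, w, axis=axis, mode="constant", cval=0.0)
        den = ndimage.correlate1d(den, w, axis=axis, mode="constant", cval=0.0)
    out = np.zeros_like(p)
    out[mask] = num[mask] / den[mask]
    return out


def postprocess_pressure(raw: PressureMap,
                         clamp_quantiles: tuple = (0.01, 0.99),
                         shift_scope: str = "global") -> PressureMap:
    """Published post-processing: binomial smoothing, quantile winsorisation,
    mean subtraction.

    The quantile bounds and the subtracted mean are computed over **all**
    masked voxels of **all** phases by default (``shift_scope="global"``);
    ``"per_phase"`` switches both to per-phase statistics.
    """
    if shift_scope not in ("global", "per_phase"):
        raise DomainError("shift_scope must be 'global' or 'per_phase'")
    mvox = raw.mask.voxels
    nt = raw.n_phases
    sm = np.zeros_like(raw.values)
    for t in range(nt):
        sm[..., t] = _binomial_smooth_phase(raw.values[..., t], mvox)

    lo_q, hi_q = clamp_quantiles
    if shift_scope == "global":
        samples = sm[mvox].ravel()
        lo, hi = np.quantile(samples, [lo_q, hi_q])
        clamped = np.clip(sm, lo, hi)
        shift = clamped[mvox].mean()
        out_vals = clamped - shift
        bounds = (float(lo), float(hi))
        shifts = np.full(nt, float(shift))
    else:
        out_vals = np.zeros_like(sm)
        los, his, shifts = [], [], np.zeros(nt)
        for t in range(nt):
            samples = sm[..., t][mvox]
            lo, hi = np.quantile(samples, [lo_q, hi_q])
            c = np.clip(sm[..., t], lo, hi)
            shifts[t] = c[mvox].mean()
            out_vals[..., t] = c - shifts[t]
            los.append(lo)
            his.append(hi)
        bounds = (float(np.min(los)), float(np.max(his)))
    out_vals[~mvox] = 0.0
    return PressureMap(values=out_vals, mask=raw.mask,
                       converged=raw.converged.copy(),
                       iterations=raw.iterations.copy(),
                       clamp_bounds=bounds, mean_shift=shifts,
                       shift_scope=shift_scope)


def helix_mask(p: PressureMap) -> HelixMask:
    """Strict P < 0 mmHg threshold within the segmentation, per phase."""
    vox = (p.values < 0) & p.mask.voxels[..., None]
    return HelixMask(voxels=vox, spacing=p.mask.spacing.copy(),
                     origin=p.mask.origin.copy())


def compute_pressure_map(fld: VelocityField4D, mask: SegmentationMask,
                         cfg: PressureSolverConfig | None = None,
                         clamp_quantiles: tuple = (0.01, 0.99),
                         shift_scope: str = "global") -> PressureMap:
    """Convenience: gradient -> relaxation -> post-processing in one call."""
    G = pressure_gradient(fld, mask, cfg)
    raw = solve_relative_pressure(G, mask, cfg)
    return postprocess_pressure(raw, clamp_quantiles, shift_scope)
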