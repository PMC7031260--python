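"""Time-resolved pathline integration through the 4D velocity field.

Pathlines are integrated with classical 4th-order Runge–Kutta in time
(step ``dt / substeps``), sampling the velocity with trilinear spatial and
linear temporal interpolation.  The field is extended cyclically over the
cardiac cycle for interpolation; integration runs forward from the seed
phase to the end of the cycle (optionally wrapping for phantoms).  A line
terminates as soon as its position leaves the segmentation mask — outside
the lumen the velocity is undefined, and zero-padding would drag lines
along the wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import DomainError
from .fields import SegmentationMask, VelocityField4D
from .pressure import HelixMask

__all__ = ["Pathline", "seed_helix", "integrate_pathlines", "filter_pathlines",
           "pathlines_to_dataframe"]


@dataclass
class Pathline:
    """Time-stamped 3D polyline.

    ``times`` in ms (strictly increasing), ``positions`` in mm.
    ``rd_label`` is set later by the rotation-direction classifier.
    """

    times: np.ndarray
    positions: np.ndarray
    seed: np.ndarray
    seed_phase: int
    in_helix_fraction: Optional[float] = None
    rd_label: str = "pending"

    def __len__(self) -> int:
        return len(self.times)


def seed_helix(hm: HelixMask, phase: int, stride: int = 1) -> np.ndarray:
    """Seed positions (mm) at the centers of every ``stride``-th flagged
    voxel of the helix mask at ``phase`` (stride 1 = densest seeding)."""
    if not (0 <= phase < hm.n_phases):
        raise DomainError(f"phase {phase} out of range [0, {hm.n_phases})")
    if stride < 1:
        raise DomainError("stride must be >= 1")
    idx = np.argwhere(hm.voxels[..., phase])
    if len(idx) == 0:
        return np.empty((0, 3))
    if stride > 1:
        keep = np.all(idx % stride == 0, axis=1)
        idx = idx[keep]
    return hm.origin + idx * hm.spacing


class _FieldSampler:
    """Trilinear-in-space, linear-in-time velocity sampler with a cyclic
    temporal extension (phase 0 repeated at t = n_phases * dt)."""

    def __init__(self, fld: VelocityField4D):
        axes = [fld.origin[d] + np.arange(fld.shape[d]) * fld.spacing[d]
                for d in range(3)]
        times = np.concatenate([fld.phase_times, [fld.n_phases * fld.dt]])
        vals = np.concatenate([fld.values, fld.values[..., :1]], axis=-1)
        self.period = fld.n_phases * fld.dt
        self._interps = [
            RegularGridInterpolator(tuple(axes) + (times,), vals[c],
                                    bounds_error=False, fill_value=0.0)
            for c in range(3)
        ]

    def __call__(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Velocity (m/s) at positions (n, 3) mm and scalar time t ms."""
        tq = np.full((len(pos), 1), t % self.period)
        q = np.hstack([pos, tq])
        return np.stack([f(q) for f in self._interps], axis=1)


def _inside_mask(mask: SegmentationMask, pos: np.ndarray) -> np.ndarray:
    idx = np.round((pos - mask.origin) / mask.spacing).astype(int)
    shape = np.array(mask.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(pos), dtype=bool)
    if ok.any():
        out[ok] = mask.voxels[tuple(idx[ok].T)]
    return out


def integrate_pathlines(fld: VelocityField4D, seeds: np.ndarray,
                        mask: SegmentationMask, substeps: int = 4,
                        start_phase: int = 0, wrap: bool = False,
                        t_end: float | None = None) -> list:
    """RK4 pathline integration from ``seeds`` at ``start_phase``.

    Parameters
    ----------
    substeps : int
        Integration steps per cardiac phase (step = dt / substeps).
    wrap : bool
        Continue cyclically past the end of the cycle (phantom use only).
    t_end : float, optional
        Integration end time in ms; defaults to the end of the cycle
        (requires ``wrap=True`` to go beyond).

    Returns
    -------
    list of Pathline; seeds outside the mask are skipped.
    """
    if substeps < 1:
        raise DomainError("substeps must be >= 1")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if len(seeds) == 0:
        return []
    sampler = _FieldSampler(fld)
    t0 = start_phase * fld.dt
    if t_end is None:
        t_end = fld.n_phases * fld.dt
    if t_end > fld.n_phases * fld.dt + 1e-9 and not wrap:
        raise DomainError("t_end beyond the cycle requires wrap=True")
    h = fld.dt / substeps
    n_steps = int(round((t_end - t0) / h))

    inside0 = _inside_mask(mask, seeds)
    seeds_in = seeds[inside0]
    n = len(seeds_in)
    if n == 0:
        return []

    pos = seeds_in.copy()
    active = np.ones(n, dtype=bool)
    traj = [pos.copy()]
    lengths = np.ones(n, dtype=int)
    t = t0
    for _ in range(n_steps):
        if not active.any():
            break
        p = pos[active]
        k1 = sampler(p, t)
        k2 = sampler(p + 0.5 * h * k1, t + 0.5 * h)
        k3 = sampler(p + 0.5 * h * k2, t + 0.5 * h)
        k4 = sampler(p + h * k3, t + h)
        p_new = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        still = _inside_mask(mask, p_new)
        idx_active = np.flatnonzero(active)
        pos[idx_active[still]] = p_new[still]
        active[idx_active[~still]] = False
        lengths[idx_active[still]] += 1
        traj.append(pos.copy())
        t += h

    traj = np.stack(traj, axis=1)  # (n, n_recorded, 3)
    times = t0 + h * np.arange(traj.shape[1])
    lines = []
    for i in range(n):
        li = lengths[i]
        if li < 2:
            continue
        lines.append(Pathline(times=times[:li].copy(),
                              positions=traj[i, :li].copy(),
                              seed=seeds_in[i].copy(),
                              seed_phase=start_phase))
    return lines


def _helix_fraction(line: Pathline, hm: HelixMask, dt: float) -> float:
    idx = np.round((line.positions - hm.origin) / hm.spacing).astype(int)
    shape = np.array(hm.voxels.shape[:3])
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    phases = np.round(line.times / dt).astype(int) % hm.n_phases
    inside = np.zeros(len(line), dtype=bool)
    if ok.any():
        inside[ok] = hm.voxels[idx[ok, 0], idx[ok, 1], idx[ok, 2], phases[ok]]
    return float(inside.mean())


def filter_pathlines(lines: list, hm: HelixMask, dt: float,
                     min_fraction: float = 0.25) -> list:
    """Keep lines that spend at least ``min_fraction`` of their samples
    inside the helix mask (nearest voxel and phase); sets
    ``in_helix_fraction`` on every input line."""
    if not (0 <= min_fraction <= 1):
        raise DomainError("min_fraction must be in [0, 1]")
    kept = []
    for line in lines:
        line.in_helix_fraction = _helix_fraction(line, hm, dt)
        if line.in_helix_fraction >= min_fraction:
            kept.append(line)
    return kept


def pathlines_to_dataframe(lines: list) -> pd.DataFrame:
    """Long-format export: line_id, t_ms, x_mm, y_mm, z_mm, rd_label."""
    rows = []
    for i, line in enumerate(lines):
        for t, p in zip(line.times, line.positions):
            rows.append((i, t, p[0], p[1], p[2], line.rd_label))
    return pd.DataFrame(rows, columns=["line_id", "t_ms", "x_mm", "y_mm",
                                       "z_mm", "rd_label"])
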