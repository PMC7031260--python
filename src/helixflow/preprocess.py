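"""Optional standard corrections applied to phase-contrast velocity data
before analysis: velocity aliasing (phase-wrap) correction, eddy-current
offset removal, and background-noise masking.

All three are off by default for phantom data, which is generated clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .errors import DomainError, UnderdeterminedError
from .fields import SegmentationMask, VelocityField4D


@dataclass
class PreprocessReport:
    n_unwrapped_voxels: int = 0
    eddy_poly_order: int | None = None
    eddy_coefficients: dict = dc_field(default_factory=dict)
    noise_mask_fraction: float = 0.0


def unwrap_phase(fld: VelocityField4D, venc_cms: float):
    """Correct velocity aliasing against a 3x3x3x3 median reference.

    A voxel whose velocity differs from the median of its spatiotemporal
    neighborhood by more than Venc is shifted by the appropriate multiple of
    2*Venc back into the +/-Venc band around the median.  A no-op on clean
    data.

    Returns (corrected VelocityField4D, PreprocessReport).
    """
    if venc_cms is None or venc_cms <= 0:
        raise DomainError("venc must be positive (cm/s)")
    venc = venc_cms / 100.0  # m/s
    out = fld.copy()
    n_fixed = 0
    for c in range(3):
        v = out.values[c]
        med = ndimage.median_filter(v, size=(3, 3, 3, 3), mode="nearest")
        wraps = np.round((v - med) / (2.0 * venc))
        bad = wraps != 0
        n_fixed += int(np.count_nonzero(bad))
        v -= 2.0 * venc * wraps
    return out, PreprocessReport(n_unwrapped_voxels=n_fixed)


def _poly_terms(coords: np.ndarray, order: int) -> np.ndarray:
    x, y, z = coords.T
    cols = [np.ones_like(x), x, y, z]
    if order == 2:
        cols += [x * x, y * y, z * z, x * y, x * z, y * z]
    return np.column_stack(cols)


def correct_eddy_currents(fld: VelocityField4D, static_mask: SegmentationMask,
                          order: int = 1):
    """Subtract a spatial polynomial background fitted on static tissue.

    Per component, a polynomial of ``order`` (1 or 2) in world coordinates is
    least-squares fitted to the temporal-mean velocity over ``static_mask``
    and subtracted from every voxel and phase — the standard correction for
    residual eddy-current phase offsets.
    """
    if order not in (1, 2):
        raise DomainError("eddy polynomial order must be 1 or 2")
    idx = np.argwhere(static_mask.voxels)
    n_terms = 4 if order == 1 else 10
    if len(idx) < n_terms:
        raise UnderdeterminedError(
            f"{len(idx)} static voxels < {n_terms} polynomial terms"
        )
    coords_static = static_mask.world_coordinates(idx)
    A = _poly_terms(coords_static, order)

    out = fld.copy()
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in fld.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    coords_all = fld.origin + grid * fld.spacing
    A_all = _poly_terms(coords_all, order)

    coeffs = {}
    for c, name in enumerate("xyz"):
        target = fld.values[c].mean(axis=-1)[tuple(idx.T)]
        beta, *_ = np.linalg.lstsq(A, target, rcond=None)
        offset = (A_all @ beta).reshape(fld.shape)
        out.values[c] -= offset[..., None]
        coeffs[name] = beta.tolist()
    return out, PreprocessReport(eddy_poly_order=order, eddy_coefficients=coeffs)


def noise_mask(fld: VelocityField4D, threshold_std: float) -> SegmentationMask:
    """Flag voxels whose temporal velocity fluctuation exceeds a threshold
    (m/s) — noise candidates outside the vessel lumen.

    The statistic is the RMS of the per-component temporal standard
    deviations (3 * (n_phases - 1) degrees of freedom), which estimates the
    per-component noise sigma far more tightly than the standard deviation
    of the speed alone.
    """
    if threshold_std <= 0:
        raise DomainError("threshold_std must be positive")
    var = fld.values.var(axis=-1, ddof=1)     # (3, nx, ny, nz)
    std = np.sqrt(var.mean(axis=0))
    flagged = std > threshold_std
    if not flagged.any():
        # SegmentationMask forbids empty masks; represent "nothing flagged"
        # as an explicit all-False array via a thin wrapper.
        m = SegmentationMask.__new__(SegmentationMask)
        m.voxels = flagged
        m.spacing = fld.spacing.copy()
        m.origin = fld.origin.copy()
        return m
    return SegmentationMask(flagged, fld.spacing.copy(), fld.origin.copy())
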