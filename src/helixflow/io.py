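"""File I/O: NIfTI velocity/mask volumes, HDF5 phantom bundles, CSV centerlines.

Velocities are converted to m/s on load (``units="cm/s"`` divides by 100);
everything downstream assumes the package-wide mm / m/s / ms / mmHg
conventions.  NIfTI affines are built as ``diag(spacing)`` plus origin —
volumes are taken as stored, with no anatomical reorientation.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .centerline import Centerline
from .errors import MetadataError, StructuralError
from .fields import SegmentationMask, VelocityField4D, cms_to_ms


def _affine(spacing, origin):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def load_case(velocity_paths, mask_path, meta: dict):
    """Load a 4D flow case from three per-component NIfTI series plus a mask.

    Parameters
    ----------
    velocity_paths : sequence of 3 paths
        One 4D NIfTI (x, y, z, phase) per velocity component, ordered x, y, z.
    mask_path : path
        Binary NIfTI segmentation on the same grid.
    meta : dict
        Required keys ``dt`` (ms) and ``cycle_length`` (ms); optional
        ``units`` ("m/s" default or "cm/s"), ``spacing``, ``origin``,
        ``venc`` (cm/s).  Spacing/origin default to the NIfTI affine.

    Returns
    -------
    (VelocityField4D, SegmentationMask)
    """
    if "dt" not in meta or "cycle_length" not in meta:
        raise MetadataError("meta must provide dt and cycle_length (ms)")
    comps = []
    for p in velocity_paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 4:
            raise StructuralError(f"{p}: expected a 4D volume, got shape {arr.shape}")
        comps.append(arr)
        affine = img.affine
    shapes = {c.shape for c in comps}
    if len(shapes) != 1:
        raise StructuralError(f"velocity components have mismatched shapes: {shapes}")
    values = np.stack(comps, axis=0)
    if str(meta.get("units", "m/s")).lower() in ("cm/s", "cms"):
        values = cms_to_ms(values)

    spacing = np.asarray(meta.get("spacing", np.abs(np.diag(affine)[:3])), dtype=float)
    origin = np.asarray(meta.get("origin", affine[:3, 3]), dtype=float)

    mask_img = nib.load(str(mask_path))
    mask_arr = np.asarray(mask_img.dataobj) > 0.5
    if mask_arr.shape != values.shape[1:4]:
        raise StructuralError(
            f"mask grid {mask_arr.shape} does not match field grid {values.shape[1:4]}"
        )
    field = VelocityField4D(
        values, spacing, float(meta["dt"]), float(meta["cycle_length"]),
        origin, meta.get("venc"),
    )
    mask = SegmentationMask(mask_arr, spacing, origin)
    return field, mask


def save_nifti(array: np.ndarray, spacing, origin, path):
    """Write a 3D/4D array as NIfTI with a diagonal affine."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(spacing, origin))
    nib.save(img, str(path))


def save_case_hdf5(path, field: VelocityField4D, mask: SegmentationMask,
                   extra: dict | None = None):
    """Write a self-contained HDF5 case bundle (used for phantoms)."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("velocity", data=field.values)
        f.create_dataset("mask", data=mask.voxels.astype(np.uint8))
        f.attrs["spacing"] = field.spacing
        f.attrs["origin"] = field.origin
        f.attrs["dt"] = field.dt
        f.attrs["cycle_length"] = field.cycle_length
        if field.venc is not None:
            f.attrs["venc"] = field.venc
        if extra:
            f.attrs["extra_json"] = json.dumps(extra, sort_keys=True)


def load_case_hdf5(path):
    """Read a bundle written by :func:`save_case_hdf5`.

    Returns (VelocityField4D, SegmentationMask, extra_dict).
    """
    with h5py.File(str(path), "r") as f:
        values = f["velocity"][()]
        voxels = f["mask"][()].astype(bool)
        spacing = np.asarray(f.attrs["spacing"], dtype=float)
        origin = np.asarray(f.attrs["origin"], dtype=float)
        dt = float(f.attrs["dt"])
        cycle = float(f.attrs["cycle_length"])
        venc = float(f.attrs["venc"]) if "venc" in f.attrs else None
        extra = json.loads(f.attrs["extra_json"]) if "extra_json" in f.attrs else {}
    field = VelocityField4D(values, spacing, dt, cycle, origin, venc)
    mask = SegmentationMask(voxels, spacing, origin)
    return field, mask, extra


def save_centerline_csv(cl: Centerline, path):
    pd.DataFrame(
        {"x_mm": cl.points[:, 0], "y_mm": cl.points[:, 1],
         "z_mm": cl.points[:, 2], "arc_mm": cl.arc_length}
    ).to_csv(path, index=False)


def load_centerline_csv(path, sampling_step: float = 1.0) -> Centerline:
    """Read an ordered-point centerline CSV (header x_mm,y_mm,z_mm[,arc_mm])."""
    df = pd.read_csv(path)
    for col in ("x_mm", "y_mm", "z_mm"):
        if col not in df.columns:
            raise MetadataError(f"centerline CSV missing column {col!r}")
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return Centerline.from_points(pts, sampling_step)
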