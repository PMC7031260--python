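"""Helix-region extraction and the quantitative helix parameters.

Within an arc-length ROI, the per-phase negative-pressure voxels are split
into 26-connected components; the temporal union of all retained voxels is
the "accumulated" helix (a temporal maximum-intensity projection).  From
these the package computes:

* ``TH_Ex`` — temporal helical existence: how long (ms, and % of cycle)
  at least one helix region exists;
* ``HV_max`` — largest instantaneous helix volume (ml, % of ROI volume)
  and the phase at which it occurs;
* ``HV_acc`` — volume of the accumulated helix (ml, %);
* ``HVL_acc`` — centerline arc length covered by the accumulated helix
  (mm, % of ROI length);
* ``HV(I)`` — helix volumes indexed to body surface area (ml/m²).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage import measure

from .centerline import Centerline, VesselROI
from .errors import DomainError, StructuralError
from .fields import SubjectMeta
from .pressure import HelixMask

__all__ = [
    "HelixRegionSet", "HelixMetrics", "extract_helix_regions",
    "temporal_helical_existence", "helical_volumes",
    "accumulated_helix_length", "helical_volume_index", "compute_helix_metrics",
]


@dataclass
class HelixRegionSet:
    """Connected helix components per phase plus their temporal union."""

    components: list               # per phase: list of (n_i, 3) voxel index arrays
    accumulated: np.ndarray        # boolean (nx, ny, nz)
    voxel_volume_mm3: float
    min_component_ml: float
    spacing: np.ndarray
    origin: np.ndarray

    @property
    def n_phases(self) -> int:
        return len(self.components)

    def phase_has_helix(self) -> np.ndarray:
        return np.array([len(c) > 0 for c in self.components])

    def phase_volume_ml(self, t: int) -> float:
        return sum(len(c) for c in self.components[t]) * self.voxel_volume_mm3 / 1000.0


@dataclass
class HelixMetrics:
    th_ex_abs_ms: float
    th_ex_rel_pct: float
    hv_series_ml: list
    hv_max_ml: float
    hv_max_pct: float
    hv_max_phase: int
    hv_acc_ml: float
    hv_acc_pct: float
    hvl_acc_mm: float
    hvl_acc_pct: float
    hvi_max_ml_m2: float | None = None
    hvi_acc_ml_m2: float | None = None

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(s + "\n")
        return s

    def to_csv_row(self) -> pd.DataFrame:
        cols = {
            "th_ex_abs_ms": self.th_ex_abs_ms,
            "th_ex_rel_pct": self.th_ex_rel_pct,
            "hv_max_ml": self.hv_max_ml,
            "hv_max_pct": self.hv_max_pct,
            "hv_acc_ml": self.hv_acc_ml,
            "hv_acc_pct": self.hv_acc_pct,
            "hvl_acc_mm": self.hvl_acc_mm,
            "hvl_acc_pct": self.hvl_acc_pct,
            "hvi_max_ml_m2": self.hvi_max_ml_m2,
            "hvi_acc_ml_m2": self.hvi_acc_ml_m2,
        }
        return pd.DataFrame([cols])


def extract_helix_regions(hm: HelixMask, roi: VesselROI,
                          min_component_ml: float = 0.0,
                          connectivity: int = 3) -> HelixRegionSet:
    """Per-phase 26-connected components of (helix mask AND ROI).

    Components smaller than ``min_component_ml`` are discarded (default 0:
    every detected region counts, regardless of size or number).  The
    accumulated set is the union of retained voxels across phases.
    """
    if hm.voxels.shape[:3] != roi.voxel_set.shape:
        raise StructuralError("helix mask grid does not match ROI grid")
    if min_component_ml < 0:
        raise DomainError("min_component_ml must be >= 0")
    vox_ml = hm.voxel_volume_mm3 / 1000.0
    min_voxels = int(np.ceil(min_component_ml / vox_ml)) if min_component_ml > 0 else 0

    components = []
    accumulated = np.zeros(roi.voxel_set.shape, dtype=bool)
    for t in range(hm.n_phases):
        phase_mask = hm.voxels[..., t] & roi.voxel_set
        comps_t = []
        if phase_mask.any():
            labels = measure.label(phase_mask, connectivity=connectivity)
            for lab in range(1, labels.max() + 1):
                idx = np.argwhere(labels == lab)
                if len(idx) >= max(min_voxels, 1):
                    comps_t.append(idx)
                    accumulated[tuple(idx.T)] = True
        components.append(comps_t)
    return HelixRegionSet(components=components, accumulated=accumulated,
                          voxel_volume_mm3=hm.voxel_volume_mm3,
                          min_component_ml=min_component_ml,
                          spacing=hm.spacing, origin=hm.origin)


def temporal_helical_existence(rs: HelixRegionSet, dt: float,
                               cycle_length: float) -> tuple:
    """(TH_Ex in ms, TH_Ex in % of cycle): dt times the number of phases with
    at least one retained helix component."""
    if dt <= 0 or cycle_length < dt:
        raise DomainError("need dt > 0 and cycle_length >= dt")
    n_present = int(rs.phase_has_helix().sum())
    th_abs = dt * n_present
    return float(th_abs), float(100.0 * th_abs / cycle_length)


def helical_volumes(rs: HelixRegionSet, roi: VesselROI) -> dict:
    """Instantaneous helix-volume series, its maximum, and the accumulated
    (temporal-union) volume, absolute (ml) and relative to the ROI volume."""
    series = np.array([rs.phase_volume_ml(t) for t in range(rs.n_phases)])
    hv_max_phase = int(np.argmax(series)) if series.size else 0
    hv_max = float(series[hv_max_phase]) if series.size else 0.0
    hv_acc = float(rs.accumulated.sum() * rs.voxel_volume_mm3 / 1000.0)
    return {
        "hv_series_ml": series.tolist(),
        "hv_max_ml": hv_max,
        "hv_max_pct": 100.0 * hv_max / roi.volume_ml,
        "hv_max_phase": hv_max_phase,
        "hv_acc_ml": hv_acc,
        "hv_acc_pct": 100.0 * hv_acc / roi.volume_ml,
    }


def accumulated_helix_length(rs: HelixRegionSet, cl: Centerline,
                             roi: VesselROI) -> tuple:
    """(HVL_acc in mm, in % of ROI length).

    Each accumulated-helix voxel maps to its nearest centerline sample and
    covers, along the arc, its own axial footprint (half the largest voxel
    edge on either side) — without the footprint, a centerline sampled
    finer than the voxel grid could never have every other sample covered.
    The covered length is the sum of the arc-length weights of covered
    samples, so an axially split helix is not bridged.  The relative value
    is capped at 100%.
    """
    if not rs.accumulated.any():
        return 0.0, 0.0
    idx = np.argwhere(rs.accumulated)
    coords = rs.origin + idx * rs.spacing
    nearest = cl.nearest_index(coords)
    covered = np.zeros(len(cl.points), dtype=bool)
    covered[nearest] = True
    # dilate along arc by the voxel half-footprint
    half_fp = float(np.max(rs.spacing)) / 2.0
    hit_arcs = cl.arc_length[covered]
    gaps = np.min(np.abs(cl.arc_length[:, None] - hit_arcs[None, :]), axis=1)
    covered |= gaps <= half_fp + 1e-9
    covered &= roi.sample_in_roi
    hvl_abs = float(cl.sample_weights()[covered].sum())
    hvl_rel = min(100.0, 100.0 * hvl_abs / roi.length_mm)
    return hvl_abs, hvl_rel


def helical_volume_index(hv_abs_ml: float, meta: SubjectMeta) -> float:
    """Helix volume normalized to body surface area, ml/m²."""
    if meta.bsa <= 0:
        raise DomainError("BSA must be positive")
    return hv_abs_ml / meta.bsa


def compute_helix_metrics(rs: HelixRegionSet, roi: VesselROI, cl: Centerline,
                          dt: float, cycle_length: float,
                          meta: SubjectMeta | None = None) -> HelixMetrics:
    """All helix parameters from an extracted region set."""
    th_abs, th_rel = temporal_helical_existence(rs, dt, cycle_length)
    hv = helical_volumes(rs, roi)
    hvl_abs, hvl_rel = accumulated_helix_length(rs, cl, roi)
    hvi_max = hvi_acc = None
    if meta is not None:
        hvi_max = helical_volume_index(hv["hv_max_ml"], meta)
        hvi_acc = helical_volume_index(hv["hv_acc_ml"], meta)
    return HelixMetrics(
        th_ex_abs_ms=th_abs, th_ex_rel_pct=th_rel,
        hv_series_ml=hv["hv_series_ml"],
        hv_max_ml=hv["hv_max_ml"], hv_max_pct=hv["hv_max_pct"],
        hv_max_phase=hv["hv_max_phase"],
        hv_acc_ml=hv["hv_acc_ml"], hv_acc_pct=hv["hv_acc_pct"],
        hvl_acc_mm=hvl_abs, hvl_acc_pct=hvl_rel,
        hvi_max_ml_m2=hvi_max, hvi_acc_ml_m2=hvi_acc,
    )
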