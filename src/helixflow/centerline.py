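"""Vessel centerline extraction and arc-length-based regions of interest.

The centerline is found as a distance-transform-weighted shortest path
through the segmentation mask between two user-supplied endpoints (the
retained piece of user interaction of a semi-automatic workflow): edge
costs on the 26-connected voxel graph are the Euclidean step length divided
by the local distance-to-wall, so the optimal path hugs the lumen center.
The raw voxel path is then smoothed with a spline and resampled at a fixed
arc-length step; tangents come from central differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, interpolate
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .errors import DomainError, EmptyRegionError, TopologyError
from .fields import SegmentationMask


@dataclass
class Centerline:
    """Ordered centerline samples with arc length and unit tangents.

    ``points`` are world coordinates in mm; ``arc_length`` is cumulative and
    starts at 0; ``tangents`` are unit vectors (the normal *n* of the
    rotation-direction cross-section frames).
    """

    points: np.ndarray
    arc_length: np.ndarray
    tangents: np.ndarray
    sampling_step: float = 1.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if len(self.points) < 2:
            raise DomainError("centerline needs at least 2 points")
        if not np.all(np.diff(self.arc_length) > 0):
            raise DomainError("arc_length must be strictly increasing")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise DomainError("tangents must be unit vectors")

    @property
    def length_mm(self) -> float:
        return float(self.arc_length[-1])

    @classmethod
    def from_points(cls, points: np.ndarray, sampling_step: float = 1.0) -> "Centerline":
        """Build a centerline from ordered points: resample at
        ``sampling_step`` (mm) along the polyline, derive tangents."""
        points = np.asarray(points, dtype=float)
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 1e-12])
        points = points[keep]
        if len(points) < 2:
            raise DomainError("degenerate centerline: fewer than 2 distinct points")
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
        n_out = max(int(round(arc[-1] / sampling_step)) + 1, 2)
        arc_out = np.linspace(0.0, arc[-1], n_out)
        pts_out = np.column_stack(
            [np.interp(arc_out, arc, points[:, d]) for d in range(3)]
        )
        tangents = np.gradient(pts_out, arc_out, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        return cls(pts_out, arc_out, tangents, sampling_step)

    def nearest_index(self, points: np.ndarray) -> np.ndarray:
        """Index of the nearest centerline sample for each query point (mm)."""
        tree = cKDTree(self.points)
        _, idx = tree.query(np.atleast_2d(points))
        return idx

    def sample_weights(self) -> np.ndarray:
        """Arc length (mm) attributed to each sample: half-intervals to the
        neighboring samples, so weights sum to the total length."""
        w = np.zeros(len(self.points))
        d = np.diff(self.arc_length)
        w[:-1] += d / 2
        w[1:] += d / 2
        return w


def _world_to_index(mask: SegmentationMask, point_mm: np.ndarray) -> tuple:
    idx = np.round((np.asarray(point_mm, float) - mask.origin) / mask.spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(mask.shape)):
        raise DomainError(f"point {point_mm} outside the image grid")
    return tuple(idx)


def compute_centerline(
    mask: SegmentationMask,
    endpoints: tuple,
    sampling_step: float = 1.0,
    smoothing: float | None = None,
) -> Centerline:
    """Distance-weighted shortest-path centerline between two endpoints.

    Parameters
    ----------
    mask : SegmentationMask
    endpoints : pair of world points (mm), both inside the mask
    sampling_step : target spacing between output samples, mm
    smoothing : spline smoothing factor; None picks one from the voxel size

    Raises
    ------
    TopologyError
        If the endpoints fall in disconnected parts of the mask.
    DomainError
        If an endpoint is outside the mask, or the endpoints coincide.
    """
    p0, p1 = (np.asarray(p, dtype=float) for p in endpoints)
    if np.allclose(p0, p1):
        raise DomainError("centerline endpoints coincide")
    i0, i1 = _world_to_index(mask, p0), _world_to_index(mask, p1)
    if not mask.voxels[i0] or not mask.voxels[i1]:
        raise DomainError("both endpoints must lie inside the mask")

    edt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)

    vox = np.argwhere(mask.voxels)
    n = len(vox)
    flat_id = -np.ones(mask.shape, dtype=np.int64)
    flat_id[tuple(vox.T)] = np.arange(n)

    offsets = np.array(
        [(dx, dy, dz)
         for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) > (0, 0, 0)]
    )
    rows, cols, costs = [], [], []
    shape = np.array(mask.shape)
    for off in offsets:
        nb = vox + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        src = np.arange(n)[ok]
        dst = flat_id[tuple(nb[ok].T)]
        valid = dst >= 0
        src, dst = src[valid], dst[valid]
        step = np.linalg.norm(off * mask.spacing)
        # inverse distance-to-wall weighting drives the path to the lumen axis
        w = step / (0.5 * (edt[tuple(vox[src].T)] + edt[tuple(vox[dst].T)]) + 1e-9)
        rows.append(src)
        cols.append(dst)
        costs.append(w)
    graph = coo_matrix(
        (np.concatenate(costs), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    s, t = flat_id[i0], flat_id[i1]
    dist, pred = dijkstra(graph, directed=False, indices=s, return_predecessors=True)
    if not np.isfinite(dist[t]):
        raise TopologyError("endpoints are disconnected within the mask")

    path = [t]
    while path[-1] != s:
        path.append(pred[path[-1]])
    path = vox[np.array(path[::-1])]
    pts = mask.origin + path * mask.spacing

    if len(pts) >= 4:
        if smoothing is None:
            # allow ~ half-voxel deviation per point
            smoothing = len(pts) * (0.5 * float(np.min(mask.spacing))) ** 2
        tck, _ = interpolate.splprep(pts.T, s=smoothing, k=3)
        u = np.linspace(0, 1, max(len(pts) * 4, 200))
        pts = np.column_stack(interpolate.splev(u, tck))
    return Centerline.from_points(pts, sampling_step)


@dataclass
class VesselROI:
    """Arc-length-bounded region of the vessel.

    Mask voxels are assigned to their nearest centerline sample; the ROI
    keeps those whose sample's arc length falls in [s_start, s_end].
    """

    s_start: float
    s_end: float
    voxel_set: np.ndarray          # boolean (nx, ny, nz)
    volume_ml: float
    length_mm: float
    centerline: Centerline
    sample_in_roi: np.ndarray      # boolean per centerline sample

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_set.sum())


def define_roi(
    mask: SegmentationMask,
    cl: Centerline,
    s_start: float | None = None,
    s_end: float | None = None,
) -> VesselROI:
    """Select the mask voxels whose nearest centerline point lies in an
    arc-length window; compute the ROI volume (ml) and length (mm)."""
    if s_start is None:
        s_start = 0.0
    if s_end is None:
        s_end = cl.length_mm
    if not (0 <= s_start < s_end <= cl.length_mm + 1e-9):
        raise DomainError(
            f"require 0 <= s_start < s_end <= {cl.length_mm}; got [{s_start}, {s_end}]"
        )
    coords = mask.world_coordinates()
    idx = cl.nearest_index(coords)
    arc = cl.arc_length[idx]
    inside = (arc >= s_start) & (arc <= s_end)
    voxel_set = np.zeros(mask.shape, dtype=bool)
    vox_idx = np.argwhere(mask.voxels)[inside]
    voxel_set[tuple(vox_idx.T)] = True
    if not voxel_set.any():
        raise EmptyRegionError("no mask voxels map into the requested arc range")
    volume_ml = voxel_set.sum() * mask.voxel_volume_mm3 / 1000.0
    sample_in_roi = (cl.arc_length >= s_start) & (cl.arc_length <= s_end)
    return VesselROI(
        s_start=float(s_start),
        s_end=float(s_end),
        voxel_set=voxel_set,
        volume_ml=float(volume_ml),
        length_mm=float(s_end - s_start),
        centerline=cl,
        sample_in_roi=sample_in_roi,
    )
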