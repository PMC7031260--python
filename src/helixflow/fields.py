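"""Core data containers and unit conventions.

Conventions used throughout the package:

* world coordinates and voxel spacing in **mm**,
* velocities in **m/s** (converted from cm/s at the I/O boundary),
* time in **ms** (temporal resolution ``dt``, cardiac cycle length),
* pressure in **mmHg**.

A convenient consequence: ``1 m/s * 1 ms = 1 mm``, so displacement in mm is
velocity (m/s) times a time step in ms with no extra factor.

Grids are regular; voxel centers define world positions
``origin + index * spacing``.  The segmentation mask shares the velocity
grid — no resampling happens anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, MetadataError, StructuralError

MMHG_PA = 133.322387415  # 1 mmHg in Pa


def cms_to_ms(values: np.ndarray) -> np.ndarray:
    """cm/s -> m/s."""
    return np.asarray(values, dtype=float) / 100.0


def ms_to_cms(values: np.ndarray) -> np.ndarray:
    """m/s -> cm/s."""
    return np.asarray(values, dtype=float) * 100.0


@dataclass
class VelocityField4D:
    """Three-component velocity on a regular 3D grid across cardiac phases.

    Parameters
    ----------
    values : ndarray, shape (3, nx, ny, nz, n_phases)
        Velocity in m/s; component axis ordered (x, y, z).
    spacing : array-like of 3 floats
        Voxel edge lengths in mm.
    dt : float
        Temporal resolution in ms.
    cycle_length : float
        Cardiac cycle duration in ms.
    origin : array-like of 3 floats, optional
        World position (mm) of voxel (0, 0, 0).
    venc : float, optional
        Velocity-encoding limit in cm/s.
    """

    values: np.ndarray
    spacing: np.ndarray
    dt: float
    cycle_length: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    venc: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 5 or self.values.shape[0] != 3:
            raise StructuralError(
                f"velocity array must be (3, nx, ny, nz, n_phases); got {self.values.shape}"
            )
        if self.n_phases < 2:
            raise MetadataError("need at least 2 cardiac phases")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise MetadataError(f"spacing must be 3 positive values; got {self.spacing}")
        if self.dt is None or self.cycle_length is None:
            raise MetadataError("dt and cycle_length are required")
        if self.dt <= 0 or self.cycle_length <= 0:
            raise MetadataError("dt and cycle_length must be positive")
        if self.dt * self.n_phases > self.cycle_length * (1 + 1e-6):
            raise MetadataError(
                f"dt*n_phases = {self.dt * self.n_phases} exceeds cycle_length {self.cycle_length}"
            )
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("velocity field contains non-finite values")

    @property
    def shape(self) -> tuple:
        """Spatial grid shape (nx, ny, nz)."""
        return self.values.shape[1:4]

    @property
    def n_phases(self) -> int:
        return self.values.shape[4]

    @property
    def phase_times(self) -> np.ndarray:
        """Time stamp (ms) of each phase: k * dt."""
        return np.arange(self.n_phases) * self.dt

    def magnitude(self) -> np.ndarray:
        """Speed |v| per voxel and phase, shape (nx, ny, nz, n_phases)."""
        return np.sqrt(np.sum(self.values**2, axis=0))

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            self.values.copy(), self.spacing.copy(), self.dt,
            self.cycle_length, self.origin.copy(), self.venc,
        )


@dataclass
class SegmentationMask:
    """Binary vessel segmentation on the velocity grid."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise StructuralError(f"mask must be 3D; got shape {self.voxels.shape}")
        if not self.voxels.any():
            raise StructuralError("segmentation mask is empty")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def world_coordinates(self, indices: np.ndarray | None = None) -> np.ndarray:
        """World positions (mm) of voxel centers.

        Parameters
        ----------
        indices : ndarray (n, 3), optional
            Voxel indices; defaults to all voxels in the mask.
        """
        if indices is None:
            indices = np.argwhere(self.voxels)
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def check_congruent(self, fld: VelocityField4D):
        if tuple(self.shape) != tuple(fld.shape):
            raise StructuralError(
                f"mask grid {self.shape} does not match field grid {fld.shape}"
            )


def body_surface_area(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m².

    DuBois–DuBois (default): ``0.007184 * W^0.425 * H^0.725``;
    Mosteller: ``sqrt(H * W / 3600)``.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * weight_kg**0.425 * height_cm**0.725
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise DomainError(f"unknown BSA formula {formula!r}")


@dataclass
class SubjectMeta:
    """Subject anthropometrics; BSA derived on construction."""

    height_cm: float
    weight_kg: float
    heart_rate: Optional[float] = None
    bsa_formula: str = "dubois"

    def __post_init__(self):
        self.bsa = body_surface_area(self.height_cm, self.weight_kg, self.bsa_formula)


@dataclass
class CaseConfig:
    """Run parameters for the end-to-end pipeline, all with documented defaults.

    Grouped by stage; every value sits within the range its consuming
    operation validates.
    """

    # pressure solver
    rho: float = 1060.0          # blood density, kg/m^3
    mu: float = 0.004            # dynamic viscosity, Pa*s
    tolerance: float = 1e-6      # max |pressure update| for convergence, mmHg
    max_iterations: int = 5000
    # pressure post-processing
    clamp_quantiles: tuple = (0.01, 0.99)
    shift_scope: str = "global"  # "global" | "per_phase"
    # helix extraction
    min_component_ml: float = 0.0
    connectivity: int = 3        # 26-neighborhood
    roi_start_mm: Optional[float] = None   # None -> whole centerline range
    roi_end_mm: Optional[float] = None
    # pathlines
    substeps: int = 4
    seed_stride: int = 1
    seed_phase: Optional[int] = None       # None -> phase of HV_max
    min_helix_fraction: float = 0.25
    # flow quantification
    plane_position: str | float = "mid"
    peak_velocity_mode: str = "magnitude"  # "magnitude" | "through_plane"
    # misc
    orientation: str = "LPS"
    seed: int = 0

    def validate(self):
        if self.rho <= 0 or self.mu <= 0:
            raise DomainError("rho and mu must be positive")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise DomainError("invalid solver tolerance/iteration cap")
        lo, hi = self.clamp_quantiles
        if not (0 <= lo < hi <= 1):
            raise DomainError("clamp quantiles must satisfy 0 <= lo < hi <= 1")
        if self.shift_scope not in ("global", "per_phase"):
            raise DomainError("shift_scope must be 'global' or 'per_phase'")
        if self.min_component_ml < 0:
            raise DomainError("min_component_ml must be >= 0")
        if self.connectivity not in (1, 2, 3):
            raise DomainError("connectivity must be 1, 2 or 3")
        if self.substeps < 1:
            raise DomainError("substeps must be >= 1")
        if not (0 <= self.min_helix_fraction <= 1):
            raise DomainError("min_helix_fraction must be in [0, 1]")
        return self
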