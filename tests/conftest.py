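"""Shared phantom fixtures.

Heavy phantoms are session-scoped so the pressure solves and pathline
integrations run once per test session.
"""

import numpy as np
import pytest

from helixflow import (CaseConfig, SegmentationMask, save_case_hdf5,
                       save_centerline_csv)
from helixflow.phantom import (PhantomSpec, SwirlSpec, make_tube_phantom,
                               preset_gated_helix, preset_poiseuille,
                               preset_rankine_steady)


@pytest.fixture(scope="session")
def poiseuille_case():
    """Steady Poiseuille tube: v_mean 0.2 m/s, R 10 mm, L 120 mm, 2 mm grid."""
    return make_tube_phantom(preset_poiseuille())


@pytest.fixture(scope="session")
def rankine_case():
    """Steady full-length Rankine swirl (pressure oracle), 2 mm grid."""
    return make_tube_phantom(preset_rankine_steady(n_phases=2))


@pytest.fixture(scope="session")
def gated_case():
    """Gated helix phantom: swirl phases 5-14 of 25, band 40-80 mm."""
    spec = preset_gated_helix()
    return make_tube_phantom(spec) + (spec,)


def small_gated_spec(seed: int = 3) -> PhantomSpec:
    """A miniature gated-swirl phantom for fast pipeline tests."""
    return PhantomSpec(
        radius_mm=8.0, length_mm=40.0, spacing_mm=2.0,
        n_phases=8, dt_ms=40.0, cycle_length_ms=320.0, v_mean=0.0,
        swirl=SwirlSpec(r_core_mm=4.0, omega_rad_s=100.0, sign=1,
                        phase_on=2, phase_off=5, z_min_mm=10.0, z_max_mm=30.0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_case_dir(tmp_path_factory):
    """On-disk HDF5 bundle + centerline CSV for the miniature phantom."""
    d = tmp_path_factory.mktemp("small_case")
    field, mask, cl, gt = make_tube_phantom(small_gated_spec())
    save_case_hdf5(d / "case.h5", field, mask,
                   extra={"ground_truth": gt.to_dict()})
    save_centerline_csv(cl, d / "centerline.csv")
    return d


@pytest.fixture()
def box_mask():
    """25 x 25 x 10 voxel box at 2 mm isotropic: exactly 6250 voxels, 50 ml."""
    vox = np.ones((25, 25, 10), dtype=bool)
    return SegmentationMask(vox, np.full(3, 2.0), np.zeros(3))
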