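"""Helix-region extraction and the quantitative helix parameters.

The accumulated ("temporal maximum-intensity projection") volume is checked
against a brute-force per-voxel logical-OR oracle throughout.
"""

import numpy as np
import pytest

from helixflow import SubjectMeta, define_roi
from helixflow.centerline import Centerline
from helixflow.metrics import (accumulated_helix_length, compute_helix_metrics,
                               extract_helix_regions, helical_volume_index,
                               helical_volumes, temporal_helical_existence)
from helixflow.phantom import ground_truth_helix_mask, make_tube_phantom
from helixflow.pressure import HelixMask


def _mask_of(shape, n_phases):
    return np.zeros(shape + (n_phases,), dtype=bool)


def _helix(vox):
    return HelixMask(voxels=vox, spacing=np.full(3, 2.0), origin=np.zeros(3))


def _box_roi(box_mask):
    cl = Centerline.from_points(np.array([[25.0, 25.0, 0.0],
                                          [25.0, 25.0, 18.0]]))
    return define_roi(box_mask, cl), cl


def brute_force_accumulated_ml(vox, voxel_volume_mm3):
    """Independent oracle: per-voxel OR across phases, then count."""
    return vox.any(axis=-1).sum() * voxel_volume_mm3 / 1000.0


class TestExtractHelixRegions:
    def test_empty_mask(self, box_mask):
        roi, _ = _box_roi(box_mask)
        rs = extract_helix_regions(_helix(_mask_of((25, 25, 10), 5)), roi)
        assert not rs.phase_has_helix().any()
        assert not rs.accumulated.any()

    def test_two_disjoint_blobs(self, box_mask):
        """Two separated 100-voxel blobs at one phase: two components of
        0.8 ml each (100 * 8 mm^3)."""
        roi, _ = _box_roi(box_mask)
        vox = _mask_of((25, 25, 10), 5)
        vox[2:7, 2:7, 2:6, 3] = True       # 5*5*4 = 100
        vox[15:20, 15:20, 2:6, 3] = True
        rs = extract_helix_regions(_helix(vox), roi)
        assert len(rs.components[3]) == 2
        for comp in rs.components[3]:
            assert len(comp) * 8 / 1000 == pytest.approx(0.8)

    def test_min_component_filter(self, box_mask):
        roi, _ = _box_roi(box_mask)
        vox = _mask_of((25, 25, 10), 5)
        vox[2:7, 2:7, 2:6, 3] = True       # 0.8 ml
        vox[20, 20, 8, 3] = True           # 0.008 ml speck
        rs = extract_helix_regions(_helix(vox), roi, min_component_ml=0.1)
        assert len(rs.components[3]) == 1

    def test_drifting_blob_union_oracle(self, box_mask):
        """A blob drifting one voxel per phase: the accumulated volume equals
        the brute-force OR volume and strictly exceeds the per-phase max."""
        roi, _ = _box_roi(box_mask)
        vox = _mask_of((25, 25, 10), 5)
        for t, z0 in zip((2, 3, 4), (2, 3, 4)):
            vox[5:10, 5:10, z0:z0 + 3, t] = True
        rs = extract_helix_regions(_helix(vox), roi)
        hv = helical_volumes(rs, roi)
        assert hv["hv_acc_ml"] == pytest.approx(
            brute_force_accumulated_ml(vox, 8.0), rel=1e-12)
        assert hv["hv_acc_ml"] > hv["hv_max_ml"]


class TestTemporalHelicalExistence:
    def test_no_helix(self, box_mask):
        roi, _ = _box_roi(box_mask)
        rs = extract_helix_regions(_helix(_mask_of((25, 25, 10), 5)), roi)
        assert temporal_helical_existence(rs, 40.0, 1000.0) == (0.0, 0.0)

    def test_all_phases_is_100_percent(self, box_mask):
        """A helix present at every phase gives a relative duration of 100%
        of the cycle — the all-phase case."""
        roi, _ = _box_roi(box_mask)
        vox = _mask_of((25, 25, 10), 5)
        vox[5:8, 5:8, 3:6, :] = True
        rs = extract_helix_regions(_helix(vox), roi)
        _, rel = temporal_helical_existence(rs, 200.0, 1000.0)
        assert rel == 100.0

    def test_gated_phantom_ground_truth(self, gated_case):
        """Swirl gated to phases 5-14 of 25 at dt 40 ms: 400 ms / 40%."""
        field, mask, cl, gt, spec = gated_case
        hm = ground_truth_helix_mask(spec)
        roi = define_roi(mask, cl)
        rs = extract_helix_regions(hm, roi)
        assert temporal_helical_existence(rs, field.dt, field.cycle_length) \
            == (400.0, 40.0)

    def test_invariant_to_component_splitting(self, box_mask):
        """TH_Ex counts phases, not components."""
        roi, _ = _box_roi(box_mask)
        one = _mask_of((25, 25, 10), 5)
        one[2:10, 2:10, 2:6, 1] = True
        split = _mask_of((25, 25, 10), 5)
        split[2:5, 2:5, 2:6, 1] = True
        split[8:10, 8:10, 2:6, 1] = True
        t1 = temporal_helical_existence(extract_helix_regions(_helix(one), roi), 40, 1000)
        t2 = temporal_helical_existence(extract_helix_regions(_helix(split), roi), 40, 1000)
        assert t1 == t2


class TestHelicalVolumes:
    def test_static_blob(self, box_mask):
        """10 ml blob at every phase in a 50 ml ROI: HV_max 10 ml / 20%,
        HV_acc identical (union of identical sets)."""
        roi, _ = _box_roi(box_mask)
        vox = _mask_of((25, 25, 10), 5)
        vox[0:25, 0:10, 0:5, :] = True     # 25*10*5 = 1250 voxels = 10 ml
        rs = extract_helix_regions(_helix(vox), roi)
        hv = helical_volumes(rs, roi)
        assert hv["hv_max_ml"] == pytest.approx(10.0)
        assert hv["hv_max_pct"] == pytest.approx(20.0)
        assert hv["hv_acc_ml"] == pytest.approx(10.0)

    def test_empty(self, box_mask):
        roi, _ = _box_roi(box_mask)
        rs = extract_helix_regions(_helix(_mask_of((25, 25, 10), 5)), roi)
        hv = helical_volumes(rs, roi)
        assert hv["hv_max_ml"] == 0 and hv["hv_acc_ml"] == 0

    def test_series_max_consistency(self, box_mask):
        roi, _ = _box_roi(box_mask)
        vox = _mask_of((25, 25, 10), 5)
        vox[2:4, 2:4, 2:4, 1] = True
        vox[2:8, 2:8, 2:5, 2] = True
        rs = extract_helix_regions(_helix(vox), roi)
        hv = helical_volumes(rs, roi)
        assert hv["hv_max_ml"] == max(hv["hv_series_ml"])
        assert hv["hv_max_phase"] == 2


class TestAccumulatedHelixLength:
    def test_gated_phantom_band(self, gated_case):
        """Swirl confined to z in [40, 80) mm of the 120 mm tube: covered
        centerline length 40 mm +/- 2 (two sampling steps)."""
        field, mask, cl, gt, spec = gated_case
        hm = ground_truth_helix_mask(spec)
        roi = define_roi(mask, cl)
        rs = extract_helix_regions(hm, roi)
        hvl_abs, hvl_rel = accumulated_helix_length(rs, cl, roi)
        assert hvl_abs == pytest.approx(40.0, abs=2.0)
        assert hvl_rel == pytest.approx(100 * hvl_abs / 120.0)

    def test_full_coverage_is_100_percent(self, box_mask):
        roi, cl = _box_roi(box_mask)
        vox = _mask_of((25, 25, 10), 3)
        vox[...] = True
        rs = extract_helix_regions(_helix(vox), roi)
        _, hvl_rel = accumulated_helix_length(rs, cl, roi)
        assert hvl_rel == 100.0

    def test_empty(self, box_mask):
        roi, cl = _box_roi(box_mask)
        rs = extract_helix_regions(_helix(_mask_of((25, 25, 10), 3)), roi)
        assert accumulated_helix_length(rs, cl, roi) == (0.0, 0.0)


class TestHelicalVolumeIndex:
    def test_simple_division(self):
        meta = SubjectMeta.__new__(SubjectMeta)
        meta.bsa = 2.0
        assert helical_volume_index(12.0, meta) == 6.0
        assert helical_volume_index(0.0, meta) == 0.0

    def test_with_dubois_bsa(self):
        """19.9 ml at the DuBois BSA of 170 cm / 70 kg (1.810 m^2)."""
        meta = SubjectMeta(height_cm=170, weight_kg=70)
        assert helical_volume_index(19.9, meta) == pytest.approx(10.99, abs=0.02)


class TestFullMetrics:
    def test_invariants_on_gated_phantom(self, gated_case):
        field, mask, cl, gt, spec = gated_case
        hm = ground_truth_helix_mask(spec)
        roi = define_roi(mask, cl)
        rs = extract_helix_regions(hm, roi)
        m = compute_helix_metrics(rs, roi, cl, field.dt, field.cycle_length,
                                  SubjectMeta(170, 70))
        assert m.hv_acc_ml >= m.hv_max_ml
        assert m.hv_acc_ml <= roi.volume_ml
        for v in (m.th_ex_rel_pct, m.hv_max_pct, m.hv_acc_pct, m.hvl_acc_pct):
            assert 0 <= v <= 100
        assert m.hvi_acc_ml_m2 == pytest.approx(m.hv_acc_ml / 1.8096, rel=1e-3)

    def test_json_and_csv_export(self, gated_case, tmp_path):
        field, mask, cl, gt, spec = gated_case
        hm = ground_truth_helix_mask(spec)
        roi = define_roi(mask, cl)
        rs = extract_helix_regions(hm, roi)
        m = compute_helix_metrics(rs, roi, cl, field.dt, field.cycle_length)
        m.to_json(tmp_path / "m.json")
        df = m.to_csv_row()
        assert (tmp_path / "m.json").exists()
        assert df.loc[0, "th_ex_abs_ms"] == 400.0
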