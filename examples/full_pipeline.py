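"""End-to-end case processing from a file bundle.

Writes a phantom case to an HDF5 bundle plus a centerline CSV, then runs
the complete chain — pressure map, P<0 helix regions, helix metrics,
pathlines, rotation direction, measuring-plane flow — and lists the
deterministic artifacts it produces.
"""

import tempfile
from pathlib import Path

from helixflow import CaseConfig, save_case_hdf5, save_centerline_csv
from helixflow.phantom import PhantomSpec, SwirlSpec, make_tube_phantom
from helixflow.pipeline import run_pipeline

spec = PhantomSpec(radius_mm=8, length_mm=40, spacing_mm=2, n_phases=8,
                   dt_ms=40, cycle_length_ms=320, v_mean=0.0,
                   swirl=SwirlSpec(r_core_mm=4, omega_rad_s=100, sign=1,
                                   phase_on=2, phase_off=5,
                                   z_min_mm=10, z_max_mm=30))
field, mask, cl, gt = make_tube_phantom(spec)

with tempfile.TemporaryDirectory() as tmp:
    case = Path(tmp) / "case"
    case.mkdir()
    save_case_hdf5(case / "case.h5", field, mask,
                   extra={"ground_truth": gt.to_dict()})
    save_centerline_csv(cl, case / "centerline.csv")

    res = run_pipeline(case, case / "results", CaseConfig(seed_stride=2))

    print("artifacts:", sorted(p.name for p in (case / "results").iterdir()))
    print(f"TH_Ex {res.metrics.th_ex_abs_ms:.0f} ms "
          f"({res.metrics.th_ex_rel_pct:.0f}%), "
          f"HV_max {res.metrics.hv_max_ml:.2f} ml, "
          f"HVL_acc {res.metrics.hvl_acc_mm:.0f} mm")
    print(f"flow: {res.flow['net_flow_ml_per_cycle']:.2f} ml/cycle, "
          f"rotation labels {res.rd_counts}")
    print("Rerunning with the same bundle and config reproduces these files")
    print("byte for byte; the log records the config hash for provenance.")
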