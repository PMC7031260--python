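"""End-to-end case runner.

``run_pipeline`` executes the full analysis chain on one case bundle —
optional preprocessing, relative pressure mapping, helix-region extraction
and metrics, pathline seeding/integration with rotation-direction
classification, and measuring-plane flow quantification — and writes
deterministic JSON/CSV artifacts.  Any stage failure is re-raised tagged
with the stage name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io as hio
from .centerline import Centerline, compute_centerline, define_roi
from .errors import HelixflowError, StageError
from .fields import CaseConfig, SegmentationMask, SubjectMeta, VelocityField4D
from .flowquant import measuring_plane, net_forward_flow, peak_velocity
from .metrics import compute_helix_metrics, extract_helix_regions
from .pathlines import filter_pathlines, integrate_pathlines, seed_helix, \
    pathlines_to_dataframe
from .preprocess import correct_eddy_currents, noise_mask, unwrap_phase
from .pressure import PressureSolverConfig, compute_pressure_map, helix_mask
from .rotation import classify_pathlines

__all__ = ["run_case", "run_pipeline", "PipelineResult"]


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False
    return _Ctx()


def _config_hash(cfg: CaseConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineResult:
    """In-memory results of one pipeline run."""

    def __init__(self):
        self.pressure = None
        self.helix = None
        self.regions = None
        self.metrics = None
        self.pathlines = []
        self.rd_counts = {}
        self.flow = {}
        self.log = {}


def run_case(field: VelocityField4D, mask: SegmentationMask,
             centerline: Centerline, cfg: CaseConfig | None = None,
             meta: SubjectMeta | None = None,
             preprocess: bool = False) -> PipelineResult:
    """Run the full analysis on in-memory inputs (see :func:`run_pipeline`
    for the file-based variant)."""
    cfg = (cfg or CaseConfig()).validate()
    res = PipelineResult()

    if preprocess:
        with _stage("preprocess"):
            if field.venc:
                field, _ = unwrap_phase(field, field.venc)

    with _stage("pressure"):
        solver = PressureSolverConfig(rho=cfg.rho, mu=cfg.mu,
                                      tolerance=cfg.tolerance,
                                      max_iterations=cfg.max_iterations)
        res.pressure = compute_pressure_map(
            field, mask, solver, cfg.clamp_quantiles, cfg.shift_scope)
        res.helix = helix_mask(res.pressure)

    with _stage("helix_metrics"):
        roi = define_roi(mask, centerline, cfg.roi_start_mm, cfg.roi_end_mm)
        res.regions = extract_helix_regions(res.helix, roi,
                                            cfg.min_component_ml,
                                            cfg.connectivity)
        res.metrics = compute_helix_metrics(res.regions, roi, centerline,
                                            field.dt, field.cycle_length, meta)

    with _stage("pathlines"):
        seed_phase = cfg.seed_phase
        if seed_phase is None:
            seed_phase = res.metrics.hv_max_phase
        seeds = seed_helix(res.helix, seed_phase, cfg.seed_stride)
        lines = integrate_pathlines(field, seeds, mask, cfg.substeps,
                                    start_phase=seed_phase)
        res.pathlines = filter_pathlines(lines, res.helix, field.dt,
                                         cfg.min_helix_fraction)

    with _stage("rotation_direction"):
        res.rd_counts = classify_pathlines(res.pathlines, centerline,
                                           cfg.orientation)

    with _stage("flow_quant"):
        plane = measuring_plane(centerline, roi, mask, cfg.plane_position)
        res.flow = {
            "net_flow_ml_per_cycle": net_forward_flow(field, plane),
            "peak_velocity_m_s": peak_velocity(field, plane,
                                               cfg.peak_velocity_mode),
            "plane_arc_mm": plane.arc_length,
        }

    res.log = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
               "n_pathlines": len(res.pathlines)}
    return res


def run_pipeline(case_dir, out_dir=None, cfg: CaseConfig | None = None,
                 meta: SubjectMeta | None = None,
                 preprocess: bool = False) -> PipelineResult:
    """File-based pipeline: read ``case.h5`` (and optional
    ``centerline.csv``) from ``case_dir``, run all stages, write
    ``metrics.json``, ``metrics.csv``, ``flow.json``, ``rd_counts.json``,
    ``pathlines.csv`` and ``log.json`` to ``out_dir``.

    Reruns with the same inputs and config produce byte-identical outputs.
    """
    case_dir = Path(case_dir)
    out_dir = Path(out_dir) if out_dir is not None else case_dir / "results"
    with _stage("io"):
        bundle = case_dir / "case.h5"
        if not bundle.exists():
            raise FileNotFoundError(f"missing case bundle {bundle}")
        field, mask, extra = hio.load_case_hdf5(bundle)
        cl_path = case_dir / "centerline.csv"
        if cl_path.exists():
            centerline = hio.load_centerline_csv(cl_path)
        else:
            ep = extra.get("centerline_endpoints")
            if ep is None:
                raise FileNotFoundError(
                    "no centerline.csv and no endpoints in the bundle")
            centerline = compute_centerline(mask, (np.asarray(ep[0]),
                                                   np.asarray(ep[1])))

    res = run_case(field, mask, centerline, cfg, meta, preprocess)

    with _stage("export"):
        out_dir.mkdir(parents=True, exist_ok=True)
        res.metrics.to_json(out_dir / "metrics.json")
        res.metrics.to_csv_row().to_csv(out_dir / "metrics.csv", index=False)
        with open(out_dir / "flow.json", "w") as f:
            json.dump(res.flow, f, indent=2, sort_keys=True)
            f.write("\n")
        with open(out_dir / "rd_counts.json", "w") as f:
            json.dump(res.rd_counts, f, indent=2, sort_keys=True)
            f.write("\n")
        pathlines_to_dataframe(res.pathlines).to_csv(
            out_dir / "pathlines.csv", index=False)
        with open(out_dir / "log.json", "w") as f:
            json.dump(res.log, f, indent=2, sort_keys=True)
            f.write("\n")
    return res
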