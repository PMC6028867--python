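"""Pipeline runner: ties surface fitting, micro simulation and the macro
combination into reproducible run artifacts.

All outputs are plain text (CSV / YAML / JSON / VTK / MSH) inside a run
directory named by the configuration hash, so any artifact can be regenerated
bit-identically from its echoed config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig, dump_config
from .fracture import ForceDisplacementCurve, run_micro_simulation
from .hexmesh import build_unit_cell_mesh, export_vtk, mesh_volume
from .macro import TorqueCurve, combine_torque, peak_torque
from .surface import ConeFit

__all__ = ["RunArtifacts", "run_dir", "write_roughness_report", "full_run",
           "sweep_gaps"]

log = logging.getLogger(__name__)


@dataclass
class RunArtifacts:
    """Everything a full run produces, in memory."""

    config: RunConfig
    fit: ConeFit
    curves: dict[float, ForceDisplacementCurve]
    torques: dict[float, TorqueCurve]
    summary: dict
    out_dir: Path | None = None


def run_dir(config: RunConfig, base=None) -> Path:
    base = Path(base if base is not None else config.raw["output_dir"])
    d = base / config.config_hash()
    d.mkdir(parents=True, exist_ok=True)
    return d


def write_roughness_report(fit: ConeFit, path) -> None:
    """CSV row with the fitted cone and the achieved roughness triple."""
    df = pd.DataFrame([{
        "mode": fit.mode,
        "sa_nm": fit.achieved.sa_nm,
        "sdq_deg": fit.achieved.sdq_deg,
        "sdr_pct": fit.achieved.sdr_pct,
        "base_radius_um": fit.cone.base_radius_um,
        "height_um": fit.cone.height_um,
        "target_sa_nm": fit.spec.sa_nm,
        "target_sdq_deg": fit.spec.sdq_deg,
        "target_sdr_pct": fit.spec.sdr_pct,
    }])
    df.to_csv(path, index=False)


def sweep_gaps(config: RunConfig, gaps_nm=None,
               write_vtk: bool = False, out: Path | None = None,
               ) -> tuple[ConeFit, dict[float, ForceDisplacementCurve]]:
    """Run the micro simulation for each gap size; returns fit and curves."""
    fit = config.fit_surface()
    micro = config.micro_config(fit.cone)
    mesh0, sets = build_unit_cell_mesh(fit.cone, config.cell,
                                       micro.target_elem_size_um)
    log.info("unit-cell mesh: %d elements, %d nodes, volume %.4g µm³",
             mesh0.n_elems, mesh0.n_nodes, mesh_volume(mesh0))
    gaps = tuple(gaps_nm) if gaps_nm is not None else config.gaps_nm
    curves: dict[float, ForceDisplacementCurve] = {}
    for gap in gaps:
        t0 = time.perf_counter()
        curve, final_mesh = run_micro_simulation(micro, gap, mesh0, sets)
        log.info("gap %g nm: %d/%d elements deleted, peak force %.4g mN "
                 "(%.1f s)", gap, int(curve.deleted_elements[-1]),
                 mesh0.n_elems, float(curve.force_mn.max()),
                 time.perf_counter() - t0)
        curves[gap] = curve
        if out is not None:
            curve.to_csv(out / f"micro_curve_gap_{gap:g}nm.csv")
            if write_vtk:
                export_vtk(final_mesh, out / f"micro_final_gap_{gap:g}nm.vtk")
    return fit, curves


def full_run(config: RunConfig, base_dir=None, write_vtk: bool = False,
             write_files: bool = True) -> RunArtifacts:
    """The whole pipeline: fit surface, sweep gaps, combine, summarize."""
    out = run_dir(config, base_dir) if write_files else None
    if out is not None:
        dump_config(config, out / "config.yaml")

    fit = config.fit_surface()
    log.info("fitted cone (%s): a=%.4g µm, h=%.4g µm; achieved "
             "Sa=%.4g nm, Sdq=%.4g°, Sdr=%.4g%%", fit.mode,
             fit.cone.base_radius_um, fit.cone.height_um,
             fit.achieved.sa_nm, fit.achieved.sdq_deg, fit.achieved.sdr_pct)
    if out is not None:
        write_roughness_report(fit, out / "roughness_report.csv")

    fit, curves = sweep_gaps(config, write_vtk=write_vtk, out=out)

    rotations = config.rotation_grid_deg()
    torques: dict[float, TorqueCurve] = {}
    summary_gaps = []
    for gap, curve in curves.items():
        tq = combine_torque(curve, config.macro, rotations)
        torques[gap] = tq
        rot_peak, t_peak = peak_torque(tq)
        summary_gaps.append({
            "gap_nm": gap,
            "peak_torque_Nmm": t_peak,
            "peak_torque_Ncm": t_peak / 10.0,
            "peak_rotation_deg": rot_peak,
            "fractured_volume_um3": float(curve.deleted_volume_um3[-1]),
            "deleted_elements": int(curve.deleted_elements[-1]),
        })
        if out is not None:
            tq.to_csv(out / f"torque_curve_gap_{gap:g}nm.csv")

    summary = {
        "profile": config.raw.get("profile"),
        "config_hash": config.config_hash(),
        "fit": {
            "mode": fit.mode,
            "base_radius_um": fit.cone.base_radius_um,
            "height_um": fit.cone.height_um,
            "achieved_sa_nm": fit.achieved.sa_nm,
            "achieved_sdq_deg": fit.achieved.sdq_deg,
            "achieved_sdr_pct": fit.achieved.sdr_pct,
        },
        "micro_total_displacement_um": config.total_displacement_um(),
        "gaps": summary_gaps,
    }
    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("run artifacts written to %s", out)
    return RunArtifacts(config, fit, curves, torques, summary, out)
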