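"""End-to-end pipeline driver: simulate → cluster-poses → fit-assay →
triage, writing every artifact plus a manifest (inputs, parameters, seed,
version, per-stage counts)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assay import ProbeSpec, cheng_prusoff, fit_dose_response, ligand_efficiency
from .config import RunConfig
from .docking import HBondCriteria, triage_report
from .io import write_json, write_poses_pdb, write_trajectory_pdb
from .pose import cluster_poses, ligand_rmsd
from .synthetic import (
    AssayGenSpec,
    TrajectoryGenSpec,
    generate_docking_poses,
    generate_dose_response,
    generate_trajectory,
    make_pocket_topology,
)

logger = logging.getLogger("posepop")

__all__ = ["run_pipeline"]


def _stage_seed(root: int, offset: int) -> int:
    return (root * 8 + offset) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run all four stages on synthetic inputs and write artifacts under
    ``config.out_dir``.  Returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }
    topo = make_pocket_topology()

    # ---- stage 1: simulate -------------------------------------------------
    sim = config.simulate
    tspec = TrajectoryGenSpec(
        n_replicates=sim.n_replicates,
        n_frames_per_replicate=sim.n_frames_per_replicate,
        frame_interval=sim.frame_interval,
        pose_weight_A=sim.pose_weight_A,
        positional_noise_sd=sim.positional_noise_sd,
        unbound_fraction=sim.unbound_fraction,
        unbound_offset=sim.unbound_offset,
        seed=_stage_seed(config.seed, 0),
    )
    traj, truth = generate_trajectory(tspec, topo)
    traj_path = out / "trajectory.pdb"
    write_trajectory_pdb(traj, traj_path, ground_truth=truth.to_dict())

    conc = np.geomspace(1e-8, 1e-8 * 10 ** 4.5, 10)  # 10 half-log dilutions
    aspec = AssayGenSpec(
        true_ic50=sim.assay_true_ic50,
        concentrations=conc,
        noise_cv=sim.assay_noise_cv,
        n_replicates=sim.assay_n_replicates,
        seed=_stage_seed(config.seed, 1),
    )
    panel = generate_dose_response(aspec)
    panel_path = out / "assay_panel.csv"
    panel.to_csv(panel_path, index=False)

    poses, scores = generate_docking_poses(
        sim.n_docking_poses, topo, sim.planted_binders,
        seed=_stage_seed(config.seed, 2),
    )
    poses_path = out / "docking_poses.pdb"
    scores_path = out / "docking_scores.csv"
    write_poses_pdb(poses, poses_path)
    scores.to_csv(scores_path, index=False)

    manifest["stages"]["simulate"] = {
        "outputs": [str(traj_path), str(panel_path), str(poses_path), str(scores_path)],
        "n_frames": traj.n_frames,
        "n_assay_records": len(panel),
        "n_docking_poses": len(poses),
    }
    logger.info("simulate: %d frames, %d assay records, %d poses",
                traj.n_frames, len(panel), len(poses))

    # ---- stage 2: cluster-poses -------------------------------------------
    clus = config.clustering
    report = cluster_poses(
        traj,
        t_start=clus.t_start,
        t_end=clus.t_end,
        interval=clus.interval,
        threshold=clus.threshold,
        k=clus.k,
        seed=_stage_seed(config.seed, 3),
    )
    cluster_path = out / "cluster_report.json"
    write_json(report.to_dict(), cluster_path)
    assign_path = out / "assignments.csv"
    report.assignments.to_csv(assign_path)

    rmsd = ligand_rmsd(traj, topo.reference_coords)
    rmsd_df = pd.DataFrame({"time_ns": rmsd.times, "median_A": rmsd.median, "mad_A": rmsd.mad})
    rmsd_path = out / "rmsd_series.csv"
    rmsd_df.to_csv(rmsd_path, index=False)

    manifest["stages"]["cluster_poses"] = {
        "inputs": [str(traj_path)],
        "outputs": [str(cluster_path), str(assign_path), str(rmsd_path)],
        "n_frames_subsampled": report.n_frames_subsampled,
        "n_frames_bound": report.n_frames_bound,
        "populations": report.populations,
    }
    logger.info("cluster-poses: %d subsampled, %d bound, populations %s",
                report.n_frames_subsampled, report.n_frames_bound, report.populations)

    # ---- stage 3: fit-assay ------------------------------------------------
    probe = ProbeSpec(
        probe_concentration=config.assay.probe_concentration,
        probe_kd=config.assay.probe_kd,
    )
    hac = int(sum(1 for a in topo.atoms if a.role == "ligand" and a.element != "H"))
    rows = []
    for (cpd, protein, assay_kind), grp in panel.groupby(["compound", "protein", "assay"]):
        fit = fit_dose_response(grp, fix_hill=config.assay.fix_hill)
        kd = le = None
        if fit.ok:
            if assay_kind == "FP" and protein in probe.probe_kd:
                kd = cheng_prusoff(fit.ic50, probe, protein)
            le = ligand_efficiency(fit.ic50, hac, config.assay.temperature)
        rows.append({
            "compound": cpd, "protein": protein, "assay": assay_kind,
            "ic50_M": fit.ic50, "kd_M": kd, "le": le,
            "ok": fit.ok, "flags": ";".join(fit.flags),
        })
    affinity = pd.DataFrame(rows)
    affinity_path = out / "affinity.csv"
    affinity.to_csv(affinity_path, index=False)
    manifest["stages"]["fit_assay"] = {
        "inputs": [str(panel_path)],
        "outputs": [str(affinity_path)],
        "n_compounds_fitted": len(affinity),
        "n_determined": int(affinity["ok"].sum()),
    }
    logger.info("fit-assay: %d fits, %d determined", len(affinity), int(affinity["ok"].sum()))

    # ---- stage 4: triage ---------------------------------------------------
    tri = config.triage
    criteria = HBondCriteria(
        max_donor_acceptor_distance=tri.max_donor_acceptor_distance,
        min_angle_at_hydrogen=tri.min_angle_at_hydrogen,
        heavy_atom_fallback_distance=tri.heavy_atom_fallback_distance,
    )
    table = triage_report(poses, topo, criteria, top_n=tri.top_n)
    selection_path = out / "docking_selection.csv"
    table.to_csv(selection_path, index=False)
    manifest["stages"]["triage"] = {
        "inputs": [str(poses_path), str(scores_path)],
        "outputs": [str(selection_path)],
        "n_poses": len(table),
        "n_selected": int(table["selected"].sum()) if len(table) else 0,
    }
    logger.info("triage: %d poses, %d selected", len(table),
                int(table["selected"].sum()) if len(table) else 0)

    write_json(manifest, out / "manifest.json")
    return manifest
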