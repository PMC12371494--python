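"""File I/O: multi-model PDB for trajectories and docking poses (via
biotite), CSV score/assay tables, and JSON sidecars.

A PDB file carries no time axis, replicate structure, or donor/acceptor
flags, so the writers emit a small JSON sidecar next to each PDB
(``<name>.pdb.json``) and the readers use it when present.  Without a
sidecar, a trajectory is read as a single replicate on a uniform time grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .docking import DockPose, PoseAtom
from .topology import AtomRecord, Topology
from .trajectory import Trajectory

__all__ = [
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_poses_pdb",
    "read_poses_pdb",
    "read_scores_csv",
    "write_json",
]

_HETERO_RES = {"LIG", "HOH"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _stack_from_traj(traj: Trajectory) -> struc.AtomArrayStack:
    n_frames, n_atoms = traj.n_frames, traj.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = traj.coords.astype(np.float32)
    stack.chain_id = np.array([a.chain for a in traj.topology.atoms])
    stack.res_id = np.array([a.res_id for a in traj.topology.atoms])
    stack.res_name = np.array([a.res_name for a in traj.topology.atoms])
    stack.atom_name = np.array([a.name for a in traj.topology.atoms])
    stack.element = np.array([a.element.upper() for a in traj.topology.atoms])
    stack.hetero = np.array(
        [a.res_name in _HETERO_RES for a in traj.topology.atoms]
    )
    return stack


def write_trajectory_pdb(traj: Trajectory, path, ground_truth: dict | None = None) -> None:
    """Multi-model PDB plus a JSON sidecar holding the time axis, replicate
    ids, and (optionally) generator ground truth."""
    path = Path(path)
    pdb = PDBFile()
    pdb.set_structure(_stack_from_traj(traj))
    pdb.write(str(path))
    sidecar = {
        "times_ns": [float(t) for t in traj.times],
        "replicate_ids": [int(r) for r in traj.replicate_ids],
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    write_json(sidecar, _sidecar_path(path))


def _role_of(res_name: str) -> str:
    if res_name == "LIG":
        return "ligand"
    if res_name == "HOH":
        return "water"
    return "protein"


def read_trajectory_pdb(path, frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-model PDB trajectory.

    Uses the JSON sidecar for times and replicate structure when present;
    otherwise assumes one replicate at ``frame_interval`` ns spacing.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    n_frames = stack.stack_depth()
    atoms = [
        AtomRecord(
            name=str(stack.atom_name[i]),
            element=str(stack.element[i]).capitalize(),
            res_name=str(stack.res_name[i]),
            res_id=int(stack.res_id[i]),
            chain=str(stack.chain_id[i]),
            role=_role_of(str(stack.res_name[i])),
        )
        for i in range(stack.array_length())
    ]
    topo = Topology(atoms=atoms, reference_coords=np.asarray(stack.coord[0], dtype=float))
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        times = np.asarray(meta["times_ns"], dtype=float)
        reps = np.asarray(meta["replicate_ids"], dtype=int)
    else:
        times = (np.arange(n_frames) + 1) * frame_interval
        reps = np.zeros(n_frames, dtype=int)
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        times=times,
        replicate_ids=reps,
        topology=topo,
    )


def write_poses_pdb(poses: list[DockPose], path) -> None:
    """Docking poses as a multi-model PDB (one model per pose) with a JSON
    sidecar carrying pose ids, energies, and donor/acceptor annotations."""
    path = Path(path)
    if poses:
        n_atoms = len(poses[0].atoms)
        if any(len(p.atoms) != n_atoms for p in poses):
            raise ValueError("all poses must share one atom set for multi-model PDB")
        stack = struc.AtomArrayStack(len(poses), n_atoms)
        stack.coord = np.array(
            [[a.xyz for a in p.atoms] for p in poses], dtype=np.float32
        )
        first = poses[0].atoms
        stack.chain_id = np.array(["L"] * n_atoms)
        stack.res_id = np.array([1] * n_atoms)
        stack.res_name = np.array(["LIG"] * n_atoms)
        stack.atom_name = np.array([a.name for a in first])
        stack.element = np.array([a.element.upper() for a in first])
        stack.hetero = np.array([True] * n_atoms)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    else:
        path.write_text("END\n")
    sidecar = {
        "pose_ids": [p.pose_id for p in poses],
        "energies": {p.pose_id: [p.e_total, p.delec] for p in poses},
        "atoms": [
            {
                "name": a.name,
                "element": a.element,
                "is_donor": a.is_donor,
                "is_acceptor": a.is_acceptor,
                "parent": a.parent,
            }
            for a in (poses[0].atoms if poses else [])
        ],
    }
    write_json(sidecar, _sidecar_path(path))


def read_poses_pdb(path, scores: pd.DataFrame | None = None) -> list[DockPose]:
    """Read docking poses written by :func:`write_poses_pdb`.

    Energies come from the ``scores`` table (columns pose_id, E_total,
    Delec) when given, else from the sidecar.
    """
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    pose_ids = meta["pose_ids"]
    if not pose_ids:
        return []
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if scores is not None:
        energies = {
            str(r.pose_id): (float(r.E_total), float(r.Delec))
            for r in scores.itertuples()
        }
    else:
        energies = {k: (float(v[0]), float(v[1])) for k, v in meta["energies"].items()}
    poses = []
    for m, pid in enumerate(pose_ids):
        e_total, delec = energies[pid]
        atoms = [
            PoseAtom(
                name=spec["name"],
                element=spec["element"],
                xyz=tuple(float(x) for x in stack.coord[m, i]),
                is_donor=spec["is_donor"],
                is_acceptor=spec["is_acceptor"],
                parent=spec["parent"],
            )
            for i, spec in enumerate(meta["atoms"])
        ]
        poses.append(DockPose(pose_id=pid, atoms=atoms, e_total=e_total, delec=delec))
    return poses


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"pose_id", "E_total", "Delec"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return df
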