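"""Synthetic trajectories, docking poses and assay panels with known truth.

The generator emulates the statistical structure the analysis assumes, not
the physics that produces it:

* a pseudo-pocket with one labelled anchor atom per recognition residue
  (Y418, D422×2, W432, C433 backbone N and O, W486, W491, D528) plus one
  structural-water site, at fixed idealized coordinates;
* a two-state ligand whose pose templates A and B are exact 180° rotations
  of each other about the exocyclic S=C bond axis, so that pose A places the
  carbonyl oxygen next to the Y418 backbone NH and pose B next to the
  structural water — the hydrogen-bond swap the two binding modes differ by;
* frames drawn from the two templates at a controllable mixture weight with
  isotropic Gaussian positional noise — per-replicate label counts are
  stratified (randomized rounding of weight × frames, positions shuffled),
  a standard variance-reduction design that keeps the realized mixture
  proportion tight at ensemble sizes of a few hundred frames while staying
  unbiased — and unbound excursions modelled as i.i.d. rigid translations
  that push the exocyclic sulfur beyond the 5 Å bound-state criterion;
* four-parameter-logistic dose–response signals with multiplicative
  Gaussian noise;
* docking pose sets in which a chosen number of "planted" poses satisfy the
  pocket pharmacophore by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .docking import DockPose, PoseAtom
from .topology import LIGAND_ATOMS, AtomRecord, Topology
from .trajectory import Trajectory

__all__ = [
    "PoseTemplate",
    "TrajectoryGenSpec",
    "TrajectoryGroundTruth",
    "AssayGenSpec",
    "make_pocket_topology",
    "pose_template",
    "generate_trajectory",
    "generate_dose_response",
    "generate_docking_poses",
    "BOUND_DISTANCE_THRESHOLD",
]

#: Bound-state criterion: exocyclic S within this distance (Å) of C433 N.
BOUND_DISTANCE_THRESHOLD = 5.0

# Ligand scaffold, pose A, Å.  Six-membered ring (radius 1.39 Å) in the
# z = 0 plane centred at the origin; the thiocarbonyl carbon C2 points toward
# the tryptophan cage (-y) with the exocyclic S1 1.68 Å further out, ring
# N-H's N1/N3 flank C2, and the carbonyl O4 sits on ring carbon C6.  The
# S=C bond lies on the y axis, which is the pose-flip axis.
_LIGAND_POSE_A = {
    "S1": (0.000, -3.070, 0.0),
    "C2": (0.000, -1.390, 0.0),
    "N1": (1.204, -0.695, 0.0),
    "N3": (-1.204, -0.695, 0.0),
    "C4": (-1.204, 0.695, 0.0),
    "C5": (0.000, 1.390, 0.0),
    "C6": (1.204, 0.695, 0.0),
    "O4": (2.270, 1.310, 0.0),
}

_LIGAND_ELEMENTS = {
    "S1": "S", "C2": "C", "N1": "N", "N3": "N",
    "C4": "C", "C5": "C", "C6": "C", "O4": "O",
}

# Pocket anchors, Å.  C433 backbone N sits 2.9 Å below S1 (bound state);
# Y418 backbone N(H) is placed 2.6 Å from the pose-A carbonyl position and
# the structural water mirrors it on the pose-B side; the D422 carboxylate
# oxygens flank the N1-H edge; the three tryptophan ring centroids cage the
# exocyclic sulfur; D528 closes the far side of the pocket.
_POCKET = [
    # (name, element, res_name, res_id, role, xyz)
    ("N", "N", "TYR", 418, "protein", (4.400, 2.600, 0.700)),
    ("H", "H", "TYR", 418, "protein", (3.578, 2.102, 0.430)),
    ("OD1", "O", "ASP", 422, "protein", (3.000, -2.400, 1.100)),
    ("OD2", "O", "ASP", 422, "protein", (3.400, -1.200, 2.000)),
    ("CEN", "C", "TRP", 432, "protein", (0.000, -3.300, 4.200)),
    ("N", "N", "CYS", 433, "protein", (0.300, -5.900, 0.400)),
    ("O", "O", "CYS", 433, "protein", (1.900, -6.600, -0.600)),
    ("CEN", "C", "TRP", 486, "protein", (3.600, -4.200, -2.600)),
    ("CEN", "C", "TRP", 491, "protein", (-3.600, -4.200, -2.600)),
    ("OD1", "O", "ASP", 528, "protein", (-3.200, -2.600, 1.400)),
    ("O", "O", "HOH", 700, "water", (-4.400, 2.600, -0.700)),
]


@dataclass(frozen=True)
class PoseTemplate:
    """Rigid ligand template for one binding pose."""

    pose_id: str                      # "A" or "B"
    coords: np.ndarray                # (len(LIGAND_ATOMS), 3), Å, LIGAND_ATOMS order

    @property
    def atom_names(self) -> tuple[str, ...]:
        return LIGAND_ATOMS


def pose_template(pose_id: str) -> PoseTemplate:
    """Ligand template for pose ``"A"`` or ``"B"``.

    Pose B is pose A rotated 180° about the exocyclic S=C bond axis
    (the y axis): (x, y, z) → (−x, y, −z).
    """
    coords = np.array([_LIGAND_POSE_A[n] for n in LIGAND_ATOMS], dtype=float)
    if pose_id == "A":
        return PoseTemplate("A", coords)
    if pose_id == "B":
        flipped = coords * np.array([-1.0, 1.0, -1.0])
        return PoseTemplate("B", flipped)
    raise ValueError(f"unknown pose {pose_id!r}; expected 'A' or 'B'")


def make_pocket_topology() -> Topology:
    """Pseudo-pocket topology with fixed, documented coordinates.

    The reference coordinate set contains the pocket anchors plus the ligand
    in pose A.  Repeated calls return identical coordinates.
    """
    atoms = [
        AtomRecord(name=n, element=e, res_name=rn, res_id=ri, chain="A", role=role)
        for (n, e, rn, ri, role, _) in _POCKET
    ]
    coords = [xyz for (*_, xyz) in _POCKET]
    for name in LIGAND_ATOMS:
        atoms.append(
            AtomRecord(
                name=name, element=_LIGAND_ELEMENTS[name],
                res_name="LIG", res_id=1, chain="L", role="ligand",
            )
        )
        coords.append(_LIGAND_POSE_A[name])
    return Topology(atoms=atoms, reference_coords=np.array(coords, dtype=float))


@dataclass
class TrajectoryGenSpec:
    """Generation parameters for a synthetic two-pose trajectory ensemble.

    Defaults mirror the study conditions the analysis was designed for:
    eight independent runs, 200 frames at 1 ns spacing each (so the second
    half of each run is a 100-frame-scale analysis window), and a bound
    two-component mixture with 0.3 Å positional noise.
    """

    n_replicates: int = 8
    n_frames_per_replicate: int = 200
    frame_interval: float = 1.0       # ns
    pose_weight_A: float = 0.5        # pose_weight_B = 1 - pose_weight_A
    positional_noise_sd: float = 0.3  # Å, isotropic per atom coordinate
    unbound_fraction: float = 0.0
    unbound_offset: float = 3.0       # Å beyond the 5 Å bound criterion
    ar1_coeff: float = 0.0            # optional AR(1) noise autocorrelation
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_frames_per_replicate < 1:
            raise ValueError("n_frames_per_replicate must be >= 1 (0-frame spec)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0.0 <= self.pose_weight_A <= 1.0:
            raise ValueError("pose_weight_A must lie in [0, 1]")
        if self.positional_noise_sd < 0:
            raise ValueError("positional_noise_sd must be >= 0")
        if not 0.0 <= self.unbound_fraction < 1.0:
            raise ValueError("unbound_fraction must lie in [0, 1)")
        if self.unbound_offset <= 0:
            raise ValueError("unbound_offset must be positive")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must lie in [0, 1)")


@dataclass
class TrajectoryGroundTruth:
    """Per-frame generating truth emitted alongside every trajectory."""

    pose_labels: np.ndarray = field(repr=False)   # "A"/"B" per frame
    bound: np.ndarray = field(repr=False)         # bool per frame
    pose_weight_A: float = 0.0
    unbound_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "pose_labels": [str(x) for x in self.pose_labels],
            "bound": [bool(x) for x in self.bound],
            "pose_weight_A": self.pose_weight_A,
            "unbound_fraction": self.unbound_fraction,
        }


def generate_trajectory(
    spec: TrajectoryGenSpec, topology: Topology
) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Draw a seeded two-pose trajectory ensemble over the pseudo-pocket.

    Each replicate receives ``round(pose_weight_A · n_frames)`` pose-A
    frames (randomized rounding of the fractional part, positions shuffled),
    so the realized mixture proportion tracks the nominal weight with
    sub-percent sampling error; protein anchors sit at their reference
    positions; i.i.d. isotropic Gaussian noise is added to every atom
    (optionally AR(1)-correlated along each replicate); with probability
    ``unbound_fraction`` the ligand is rigidly translated along the
    C433(N)→S direction so that the nominal S–C433(N) distance equals
    5 Å + ``unbound_offset``.  Frame times are (i+1)·frame_interval ns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ref = topology.reference_coords
    lig_idx = topology.ligand_indices
    s1 = topology.ligand_index("S1")
    c433_n = topology.index(433, "N")

    templates = {"A": pose_template("A").coords, "B": pose_template("B").coords}
    n_rep, n_frm = spec.n_replicates, spec.n_frames_per_replicate
    n_total = n_rep * n_frm
    n_atoms = topology.n_atoms

    coords = np.empty((n_total, n_atoms, 3))
    times = np.empty(n_total)
    reps = np.empty(n_total, dtype=int)
    labels = np.empty(n_total, dtype="U1")
    bound = np.empty(n_total, dtype=bool)

    # direction that pushes the ligand out of the bound state
    away = ref[s1] - ref[c433_n]
    away /= np.linalg.norm(away)

    i = 0
    for rep in range(n_rep):
        # stratified label counts: floor(w*n) plus randomized rounding
        exact = spec.pose_weight_A * n_frm
        n_a = int(np.floor(exact)) + int(rng.random() < (exact - np.floor(exact)))
        rep_labels = np.array(["A"] * n_a + ["B"] * (n_frm - n_a))
        rng.shuffle(rep_labels)
        noise_prev = None
        for f in range(n_frm):
            frame = ref.copy()
            lab = str(rep_labels[f])
            frame[lig_idx] = templates[lab]
            is_unbound = rng.random() < spec.unbound_fraction
            if is_unbound:
                target = ref[c433_n] + away * (
                    BOUND_DISTANCE_THRESHOLD + spec.unbound_offset
                )
                frame[lig_idx] += target - frame[s1]
            eps = rng.normal(0.0, spec.positional_noise_sd, size=(n_atoms, 3))
            if spec.ar1_coeff > 0 and noise_prev is not None:
                eps = spec.ar1_coeff * noise_prev + np.sqrt(1 - spec.ar1_coeff**2) * eps
            noise_prev = eps
            frame += eps
            coords[i] = frame
            times[i] = (f + 1) * spec.frame_interval
            reps[i] = rep
            labels[i] = lab
            bound[i] = not is_unbound
            i += 1

    traj = Trajectory(coords=coords, times=times, replicate_ids=reps, topology=topology)
    truth = TrajectoryGroundTruth(
        pose_labels=labels, bound=bound,
        pose_weight_A=spec.pose_weight_A, unbound_fraction=spec.unbound_fraction,
    )
    return traj, truth


@dataclass
class AssayGenSpec:
    """Four-parameter-logistic dose–response generation parameters."""

    true_ic50: float                          # M
    concentrations: np.ndarray                # M, strictly positive, sorted
    hill_slope: float = 1.0
    top: float = 1.0                          # signal at c -> 0
    bottom: float = 0.0                       # signal at c -> inf
    noise_cv: float = 0.0                     # multiplicative Gaussian CV
    n_replicates: int = 4
    seed: int = 0

    def validate(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be positive")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.noise_cv < 0 or self.n_replicates < 1:
            raise ValueError("noise_cv must be >= 0 and n_replicates >= 1")


def four_param_logistic(
    c: np.ndarray, ic50: float, hill: float, top: float, bottom: float
) -> np.ndarray:
    """Decreasing 4PL: top at c→0, bottom at c→∞, midpoint at c = IC50."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def generate_dose_response(
    spec: AssayGenSpec,
    compound: str = "CPD",
    protein: str = "DF2",
    assay: str = "FP",
) -> pd.DataFrame:
    """Seeded dose–response panel as a tidy frame
    (compound, protein, assay, conc_M, signal, replicate).

    signal(c) = bottom + (top−bottom)/(1+(c/IC50)^hill) · (1+ε), ε ~ N(0, noise_cv),
    applied to the window term, replicate by replicate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    rows = []
    for r in range(spec.n_replicates):
        frac = (spec.top - spec.bottom) / (1.0 + (c / spec.true_ic50) ** spec.hill_slope)
        eps = rng.normal(0.0, spec.noise_cv, size=c.size) if spec.noise_cv > 0 else 0.0
        signal = spec.bottom + frac * (1.0 + eps)
        for ci, si in zip(c, signal):
            rows.append((compound, protein, assay, ci, si, r))
    return pd.DataFrame(
        rows, columns=["compound", "protein", "assay", "conc_M", "signal", "replicate"]
    )


def generate_docking_poses(
    n: int,
    topology: Topology,
    planted_binders: int,
    seed: int = 0,
) -> tuple[list[DockPose], pd.DataFrame]:
    """Docking pose set with exactly ``planted_binders`` pharmacophore hits.

    Planted poses carry a donor N–H aimed at the C433 backbone O (2.9 Å,
    near-linear) and an acceptor O reached by the Y418 backbone NH; decoys
    place the donor ~6.5 Å from the carbonyl so the mandatory hydrogen bond
    fails.  Planted poses also draw more favorable (more negative) values of
    both energy terms.  The score table flags the ground truth.
    """
    if planted_binders > n or planted_binders < 0 or n < 0:
        raise ValueError("require 0 <= planted_binders <= n")
    rng = np.random.default_rng(seed)
    ref = topology.reference_coords
    c433_o = ref[topology.index(433, "O")]
    c433_n = ref[topology.index(433, "N")]
    y418_n = ref[topology.index(418, "N")]
    y418_h = ref[topology.index(418, "H")]

    u = c433_o - c433_n
    u /= np.linalg.norm(u)                       # out of the pocket past the carbonyl
    v = y418_h - y418_n
    v /= np.linalg.norm(v)                       # along the Y418 N-H bond

    binder_flags = np.zeros(n, dtype=bool)
    binder_flags[:planted_binders] = True
    rng.shuffle(binder_flags)

    poses: list[DockPose] = []
    rows = []
    for i in range(n):
        pid = f"P{i:03d}"
        is_binder = bool(binder_flags[i])
        jitter = rng.normal(0.0, 0.05, size=3)
        if is_binder:
            nd = c433_o + u * 2.9 + jitter
            hd = nd - u * 1.0                    # H between donor and acceptor
            oa = y418_n + v * 2.6 + rng.normal(0.0, 0.05, size=3)
            e_total = rng.normal(-18.0, 0.8)
            delec = rng.normal(-9.0, 0.6)
        else:
            nd = c433_o + u * 6.5 + jitter
            hd = nd - u * 1.0
            oa = nd + np.array([1.5, 0.0, 0.0]) + rng.normal(0.0, 0.05, size=3)
            e_total = rng.normal(-12.0, 1.5)
            delec = rng.normal(-5.0, 1.2)
        atoms = [
            PoseAtom("ND", "N", tuple(nd), is_donor=True),
            PoseAtom("HD", "H", tuple(hd), parent="ND"),
            PoseAtom("OA", "O", tuple(oa), is_acceptor=True),
            PoseAtom("C1", "C", tuple(nd + np.array([0.0, 1.4, 0.0]))),
        ]
        poses.append(DockPose(pose_id=pid, atoms=atoms, e_total=e_total, delec=delec))
        rows.append((pid, e_total, delec, is_binder))

    scores = pd.DataFrame(rows, columns=["pose_id", "E_total", "Delec", "is_binder"])
    return poses, scores
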