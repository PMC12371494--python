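"""Post-docking hit triage for the m6A pocket.

Docked fragments arrive with two precomputed energy terms — the total binding
energy and the electrostatic-interaction-minus-ligand-desolvation term
(``Delec``) — and are shortlisted by taking the union of the top ``n`` of the
two independent rankings, then filtered by the pharmacophoric hydrogen-bond
pattern of the pocket: a ligand donor must reach the C433 backbone carbonyl
(the acceptor that reads the N6 of m6A), plus at least one secondary polar
contact with the Y418 backbone NH, the D422 carboxylate, or the conserved
structural water.

Energy terms are *inputs*: no docking energy function is evaluated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import Topology

__all__ = [
    "PoseAtom",
    "DockPose",
    "HBondCriteria",
    "HBondGeometry",
    "Interaction",
    "FilterResult",
    "detect_hbond",
    "rank_poses",
    "pharmacophore_filter",
    "triage_report",
]


@dataclass(frozen=True)
class PoseAtom:
    """Ligand atom of a docked pose.

    ``parent`` names the heavy atom a hydrogen is bonded to (None for heavy
    atoms); donor/acceptor flags are carried by the heavy atoms.
    """

    name: str
    element: str
    xyz: tuple[float, float, float]
    is_donor: bool = False
    is_acceptor: bool = False
    parent: str | None = None

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class DockPose:
    pose_id: str
    atoms: list[PoseAtom]
    e_total: float   # kcal/mol, total binding energy
    delec: float     # kcal/mol, electrostatic interaction minus ligand desolvation

    def __post_init__(self) -> None:
        if not (math.isfinite(self.e_total) and math.isfinite(self.delec)):
            raise ValueError(f"pose {self.pose_id}: non-finite energy terms")
        for a in self.atoms:
            if not np.all(np.isfinite(a.coord)):
                raise ValueError(f"pose {self.pose_id}: non-finite coordinates for atom {a.name}")

    def donors(self) -> list[tuple[PoseAtom, PoseAtom | None]]:
        """(heavy donor, bonded hydrogen or None) pairs."""
        hydrogens = {a.parent: a for a in self.atoms if a.element == "H" and a.parent}
        return [(a, hydrogens.get(a.name)) for a in self.atoms if a.is_donor]

    def acceptors(self) -> list[PoseAtom]:
        return [a for a in self.atoms if a.is_acceptor]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond cutoffs (donor–acceptor distance in Å,
    donor–H–acceptor angle in degrees, heavy-atom-only fallback in Å)."""

    max_donor_acceptor_distance: float = 3.5
    min_angle_at_hydrogen: float = 120.0
    heavy_atom_fallback_distance: float = 3.5

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0 or self.heavy_atom_fallback_distance <= 0:
            raise ValueError("hydrogen-bond distance cutoffs must be positive")
        if not 0 < self.min_angle_at_hydrogen <= 180:
            raise ValueError("min_angle_at_hydrogen must be in (0, 180]")


@dataclass(frozen=True)
class HBondGeometry:
    is_hbond: bool
    distance: float           # donor–acceptor heavy-atom distance, Å
    angle: float | None       # donor–H–acceptor angle, degrees; None without H


@dataclass(frozen=True)
class Interaction:
    partner: str              # "C433" | "Y418" | "D422" | "water"
    ligand_atom: str
    distance: float
    angle: float | None


@dataclass
class FilterResult:
    keep: bool
    fingerprint: list[Interaction] = field(default_factory=list)

    def partners(self) -> list[str]:
        return [i.partner for i in self.fingerprint]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u, v = a - b, c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def detect_hbond(
    donor: np.ndarray | PoseAtom,
    hydrogen: np.ndarray | PoseAtom | None,
    acceptor: np.ndarray | PoseAtom,
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondGeometry:
    """Geometric hydrogen-bond test.

    With an explicit hydrogen the bond requires donor–acceptor distance
    ≤ ``max_donor_acceptor_distance`` and donor–H–acceptor angle
    ≥ ``min_angle_at_hydrogen``; without one, only the heavy-atom distance
    against ``heavy_atom_fallback_distance``.  The measured geometry is
    returned either way.
    """
    d = donor.coord if isinstance(donor, PoseAtom) else np.asarray(donor, dtype=float)
    a = acceptor.coord if isinstance(acceptor, PoseAtom) else np.asarray(acceptor, dtype=float)
    if np.allclose(d, a):
        raise ValueError("donor and acceptor are the same atom")
    dist = float(np.linalg.norm(d - a))
    if hydrogen is None:
        return HBondGeometry(dist <= criteria.heavy_atom_fallback_distance, dist, None)
    h = hydrogen.coord if isinstance(hydrogen, PoseAtom) else np.asarray(hydrogen, dtype=float)
    ang = _angle_deg(d, h, a)
    ok = dist <= criteria.max_donor_acceptor_distance and ang >= criteria.min_angle_at_hydrogen
    return HBondGeometry(ok, dist, ang)


def _rank_table(poses: list[DockPose]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "pose_id": [p.pose_id for p in poses],
            "e_total": [p.e_total for p in poses],
            "delec": [p.delec for p in poses],
        }
    )
    # ascending energies: rank 1 = most favorable; ties broken by pose_id
    for col, rank_col in (("e_total", "rank_e_total"), ("delec", "rank_delec")):
        order = df.sort_values([col, "pose_id"], kind="mergesort").index
        ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
        df[rank_col] = ranks.sort_index().to_numpy()
    return df


def rank_poses(poses: list[DockPose], top_n: int) -> pd.DataFrame:
    """Shortlist by the union of the two energy rankings.

    Returns the shortlisted poses (top ``top_n`` of the ascending e_total
    ranking, union top ``top_n`` of the ascending Delec ranking) annotated
    with both ranks, ordered by best rank then pose_id.
    """
    if not poses:
        raise ValueError("rank_poses requires at least one pose")
    df = _rank_table(poses)
    keep = (df["rank_e_total"] <= top_n) | (df["rank_delec"] <= top_n)
    short = df[keep].copy()
    short["best_rank"] = short[["rank_e_total", "rank_delec"]].min(axis=1)
    short = short.sort_values(["best_rank", "pose_id"], kind="mergesort")
    return short.drop(columns="best_rank").reset_index(drop=True)


def pharmacophore_filter(
    pose: DockPose,
    pocket: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> FilterResult:
    """Keep a pose iff it hydrogen-bonds the C433 backbone carbonyl *and*
    makes at least one secondary polar contact (Y418 backbone NH → ligand
    acceptor, ligand donor → D422 carboxylate, or either polarity with the
    structural water, tested on heavy atoms only since the water hydrogens
    are not resolved)."""
    ref = pocket.reference_coords
    c433_o = ref[pocket.index(433, "O")]
    y418_n = ref[pocket.index(418, "N")]
    try:
        y418_h = ref[pocket.index(418, "H")]
    except KeyError:
        y418_h = None
    d422 = [ref[pocket.index(422, "OD1")], ref[pocket.index(422, "OD2")]]
    water_idx = pocket.indices_where("water")
    if water_idx.size == 0:
        raise KeyError("structural water O not in pocket topology")
    water_o = ref[water_idx[0]]

    fingerprint: list[Interaction] = []

    # mandatory: ligand donor -> C433 backbone O
    for donor, hyd in pose.donors():
        g = detect_hbond(donor, hyd, c433_o, criteria)
        if g.is_hbond:
            fingerprint.append(Interaction("C433", donor.name, g.distance, g.angle))
            break
    has_c433 = bool(fingerprint)

    # secondary: Y418 NH -> ligand acceptor
    for acc in pose.acceptors():
        g = detect_hbond(y418_n, y418_h, acc.coord, criteria)
        if g.is_hbond:
            fingerprint.append(Interaction("Y418", acc.name, g.distance, g.angle))
            break
    # secondary: ligand donor -> D422 carboxylate
    done = False
    for donor, hyd in pose.donors():
        for o in d422:
            g = detect_hbond(donor, hyd, o, criteria)
            if g.is_hbond:
                fingerprint.append(Interaction("D422", donor.name, g.distance, g.angle))
                done = True
                break
        if done:
            break
    # secondary: ligand donor or acceptor <-> structural water (heavy atoms)
    polar = {a.name: a for a, _ in pose.donors()}
    polar.update({a.name: a for a in pose.acceptors()})
    for atom in polar.values():
        g = detect_hbond(atom.coord, None, water_o, criteria)
        if g.is_hbond:
            fingerprint.append(Interaction("water", atom.name, g.distance, g.angle))
            break

    secondary = {i.partner for i in fingerprint} - {"C433"}
    return FilterResult(keep=has_c433 and bool(secondary), fingerprint=fingerprint)


def triage_report(
    poses: list[DockPose],
    pocket: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    top_n: int = 50,
) -> pd.DataFrame:
    """Full selection table: both energy ranks, filter verdict and
    fingerprint for every pose; ``selected`` = shortlisted ∩ filter-pass."""
    cols = [
        "pose_id", "e_total", "delec", "rank_e_total", "rank_delec",
        "shortlisted", "filter_keep", "fingerprint", "selected",
    ]
    if not poses:
        return pd.DataFrame(columns=cols)
    df = _rank_table(poses)
    df["shortlisted"] = (df["rank_e_total"] <= top_n) | (df["rank_delec"] <= top_n)
    verdicts, prints = [], []
    for p in poses:
        res = pharmacophore_filter(p, pocket, criteria)
        verdicts.append(res.keep)
        prints.append(";".join(res.partners()))
    df["filter_keep"] = verdicts
    df["fingerprint"] = prints
    df["selected"] = df["shortlisted"] & df["filter_keep"]
    return df[cols].sort_values("pose_id", kind="mergesort").reset_index(drop=True)
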