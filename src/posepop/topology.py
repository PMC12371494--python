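"""Atom topology for the m6A-reader pocket and the thiourea-ring ligand.

The analysis pipeline only needs a small set of labelled anchor atoms on the
protein side (the aromatic-cage tryptophans, the C433 backbone N/O that define
the bound-state criterion and the crucial hydrogen bond, the D422 carboxylate,
the Y418 backbone NH, D528, and one structural water) plus the heavy atoms of
the ligand scaffold.  A :class:`Topology` carries those labels, per-atom role
flags, and a fixed reference coordinate set for the pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "FEATURE_COLUMNS",
    "FEATURE_PAIRS",
    "LIGAND_ATOMS",
]

#: Fixed column order of the 10-distance feature matrix.
FEATURE_COLUMNS = (
    "C433_1", "C433_2", "C433_3", "C433_4",
    "D422_1", "D422_2",
    "Y418", "W432", "W486", "W491",
)

#: Ligand scaffold heavy atoms: exocyclic sulfur S1 on the thiocarbonyl C2,
#: ring N-H nitrogens N1/N3 flanking C2, carbonyl O4 on ring carbon C6.
LIGAND_ATOMS = ("S1", "C2", "N1", "N3", "C4", "C5", "C6", "O4")

#: Default atom-to-atom pairs behind each feature column:
#: (column, ligand atom, (residue id, protein atom)).  Four distances anchor
#: the scaffold to C433 (backbone N and O), the two ring N-H's to the D422
#: carboxylate oxygens, and the exocyclic sulfur to Y418's backbone N and the
#: three tryptophan ring centroids of the aromatic cage.
FEATURE_PAIRS = (
    ("C433_1", "S1", (433, "N")),
    ("C433_2", "O4", (433, "O")),
    ("C433_3", "N1", (433, "N")),
    ("C433_4", "N3", (433, "O")),
    ("D422_1", "N1", (422, "OD1")),
    ("D422_2", "N3", (422, "OD2")),
    ("Y418", "S1", (418, "N")),
    ("W432", "S1", (432, "CEN")),
    ("W486", "S1", (486, "CEN")),
    ("W491", "S1", (491, "CEN")),
)


@dataclass(frozen=True)
class AtomRecord:
    """One labelled atom: PDB-style naming plus a role flag."""

    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    role: str  # "protein" | "ligand" | "water"


@dataclass
class Topology:
    """Labelled atom set with fixed reference coordinates (Å).

    ``reference_coords`` holds the idealized pocket geometry with the ligand
    in pose A; trajectory frames supply their own coordinates but share the
    atom ordering defined here.
    """

    atoms: list[AtomRecord]
    reference_coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.reference_coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"reference_coords shape {self.reference_coords.shape} does not "
                f"match atom count {len(self.atoms)}"
            )
        names = [(a.res_id, a.name) for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate (res_id, atom_name) labels in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index(self, res_id: int, atom_name: str) -> int:
        """Index of the atom with the given residue id and name.

        Raises ``KeyError`` naming the missing anchor — downstream operations
        rely on this to produce actionable errors when a topology lacks a
        required anchor.
        """
        for i, a in enumerate(self.atoms):
            if a.res_id == res_id and a.name == atom_name:
                return i
        raise KeyError(f"anchor atom {atom_name} of residue {res_id} not in topology")

    def indices_where(self, role: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.role == role], dtype=int)

    @property
    def ligand_indices(self) -> np.ndarray:
        return self.indices_where("ligand")

    @property
    def protein_indices(self) -> np.ndarray:
        return self.indices_where("protein")

    def ligand_index(self, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.role == "ligand" and a.name == atom_name:
                return i
        raise KeyError(f"ligand atom {atom_name} not in topology")

    def feature_pair_indices(self) -> list[tuple[str, int, int]]:
        """(column, ligand index, protein index) for the 10 default distances."""
        out = []
        for col, lig_name, (res_id, atom_name) in FEATURE_PAIRS:
            out.append((col, self.ligand_index(lig_name), self.index(res_id, atom_name)))
        return out
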