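"""Trajectory container shared by the synthetic generator and the analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Topology

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Coordinate frames over a labelled topology.

    coords : (n_frames, n_atoms, 3) float array, Å
    times  : per-frame simulation time, ns; strictly increasing within each
             replicate
    replicate_ids : per-frame integer replicate label (several independent MD
             runs may be pooled into one Trajectory)
    """

    coords: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    replicate_ids: np.ndarray = field(repr=False)
    topology: Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )
        n = self.coords.shape[0]
        if self.times.shape != (n,) or self.replicate_ids.shape != (n,):
            raise ValueError("times and replicate_ids must be per-frame")
        for rep in np.unique(self.replicate_ids):
            t = self.times[self.replicate_ids == rep]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing in replicate {rep}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select_frames(self, mask_or_indices) -> "Trajectory":
        """New trajectory restricted to the given frames (topology shared)."""
        idx = np.asarray(mask_or_indices)
        return Trajectory(
            coords=self.coords[idx],
            times=self.times[idx],
            replicate_ids=self.replicate_ids[idx],
            topology=self.topology,
        )

    def frame_keys(self) -> list[tuple[int, int]]:
        """Per-frame (replicate_id, frame_index) keys, frame index counted
        within each replicate in time order."""
        keys: list[tuple[int, int]] = []
        counters: dict[int, int] = {}
        for rep in self.replicate_ids:
            r = int(rep)
            k = counters.get(r, 0)
            keys.append((r, k))
            counters[r] = k + 1
        return keys
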