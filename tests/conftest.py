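import numpy as np
import pytest

from posepop.synthetic import (
    TrajectoryGenSpec,
    generate_trajectory,
    make_pocket_topology,
)
from posepop.trajectory import Trajectory


@pytest.fixture(scope="session")
def topo():
    return make_pocket_topology()


@pytest.fixture
def make_traj(topo):
    """Factory for seeded synthetic trajectories over the standard pocket."""

    def _make(**kwargs) -> tuple:
        spec = TrajectoryGenSpec(**kwargs)
        return generate_trajectory(spec, topo)

    return _make


@pytest.fixture
def two_template_traj(topo):
    """Noise-free trajectory alternating pose A and pose B frames."""
    from posepop.synthetic import pose_template

    ref = topo.reference_coords
    lig = topo.ligand_indices
    n = 20
    coords = np.repeat(ref[None], n, axis=0)
    labels = []
    for i in range(n):
        pose = "A" if i % 2 == 0 else "B"
        coords[i, lig] = pose_template(pose).coords
        labels.append(pose)
    traj = Trajectory(
        coords=coords,
        times=np.arange(1, n + 1, dtype=float),
        replicate_ids=np.zeros(n, dtype=int),
        topology=topo,
    )
    return traj, labels
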