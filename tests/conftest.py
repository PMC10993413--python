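import numpy as np
import pytest

from samsurf.traj_io import BoxSpec, Frame, Topology, Trajectory


def make_topology(roles, molecule_id=None, species=None):
    roles = list(roles)
    n = len(roles)
    return Topology(
        roles=np.array(roles, dtype=object),
        molecule_id=np.arange(n) if molecule_id is None else np.asarray(molecule_id),
        species=np.array(["X"] * n if species is None else species, dtype=object),
    )


def make_trajectory(positions_per_frame, topology, box, dt=1.0):
    frames = [
        Frame(time=i * dt, positions=np.asarray(p, dtype=float), box=box)
        for i, p in enumerate(positions_per_frame)
    ]
    return Trajectory(topology=topology, frames=frames)


@pytest.fixture
def slab_box():
    return BoxSpec(40.0, 40.0, 25.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
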