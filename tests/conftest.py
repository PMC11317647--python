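import numpy as np
import pytest

from permkit.core import Frame, PoreSpec, Topology, Trajectory


def make_topology(names, resnames=None, resids=None, chains=None,
                  elements=None, species=None):
    n = len(names)
    return Topology(
        names=np.asarray(names),
        elements=np.asarray(elements if elements is not None
                            else [str(x)[0] for x in names]),
        resnames=np.asarray(resnames if resnames is not None else ["UNK"] * n),
        resids=np.asarray(resids if resids is not None else np.arange(1, n + 1)),
        chains=np.asarray(chains if chains is not None else ["A"] * n),
        species=np.asarray(species if species is not None else ["other"] * n),
    )


def make_traj(frames_positions, topology, box=(50.0, 50.0, 50.0), dt=1.0):
    """Build a Trajectory from a list of (n_atoms, 3) arrays."""
    frames = [
        Frame(time=i * dt, positions=np.asarray(p, dtype=float),
              box=np.asarray(box, dtype=float))
        for i, p in enumerate(frames_positions)
    ]
    return Trajectory(frames=frames, topology=topology, dt=dt)


@pytest.fixture
def tiny_traj():
    """3 frames, 1 Na+ and 2 water oxygens in a 30 Å box."""
    top = make_topology(
        names=["NA", "OW", "OW"],
        resnames=["SOD", "SOL", "SOL"],
        resids=[1, 2, 3],
        elements=["NA", "O", "O"],
        species=["cation", "water-oxygen", "water-oxygen"],
    )
    base = np.array([[15.0, 15.0, 15.0], [18.0, 15.0, 15.0], [15.0, 19.0, 15.0]])
    frames = [base + i * 0.1 for i in range(3)]
    return make_traj(frames, top, box=(30.0, 30.0, 30.0), dt=0.5)


@pytest.fixture
def default_pore():
    return PoreSpec(z_sf=10.0, z_gate=-10.0)
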