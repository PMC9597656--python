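import numpy as np
import pytest

from memtilt.io_model import Atom, Frame, Topology, Trajectory, standard_groups
from memtilt.synthetic_data import (CapacitorSpec, TwoStateSpec, gen_capacitor,
                                    gen_mock_bilayer, gen_two_state_helix)


@pytest.fixture(scope="session")
def capacitor():
    """Static parallel-plate fixture with analytic TMP truth."""
    spec = CapacitorSpec(box=(40.0, 40.0, 80.0), z1=30.0, z2=50.0,
                         sigma=0.01, charges_per_plate=64)
    traj, truth = gen_capacitor(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def mock_bilayer():
    return gen_mock_bilayer(n_lipids=100, n_waters=1500,
                            anionic_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def two_state():
    spec = TwoStateSpec(seed=42)
    traj, tmp_series, truth = gen_two_state_helix(spec)
    return spec, traj, tmp_series, truth


def point_system(positions, charges=None, masses=None, box=(10.0, 10.0, 10.0),
                 residue_indices=None, time=0.0):
    """Tiny ad-hoc system of point particles for geometry tests."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = positions.shape[0]
    charges = charges if charges is not None else [0.0] * n
    masses = masses if masses is not None else [1.0] * n
    resids = residue_indices if residue_indices is not None else range(1, n + 1)
    atoms = [Atom(name=f"X{i}", residue_index=int(r), residue_name="DUM",
                  charge=float(q), mass=float(m))
             for i, (r, q, m) in enumerate(zip(resids, charges, masses))]
    top = standard_groups(Topology(atoms, charges_assigned=True))
    frame = Frame(time=time, coordinates=positions, box=np.asarray(box))
    return top, frame


@pytest.fixture
def make_point_system():
    return point_system


def single_frame_traj(top, frame):
    return Trajectory(topology=top, frames=[frame])
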