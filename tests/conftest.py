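import numpy as np
import pytest

from barrelens.ensemble_io import AtomKey, Conformer, ConformerEnsemble


@pytest.fixture(scope="session")
def topo20():
    from barrelens.synthetic_data import make_topology

    return make_topology(20)


@pytest.fixture(scope="session")
def topo32():
    from barrelens.synthetic_data import make_topology

    return make_topology(32)


def make_conformer(spec, model_id=1):
    """Build a Conformer from [(resnum, resname, atomname, xyz), ...]."""
    atoms = [AtomKey(r, n, a) for r, n, a, _ in spec]
    coords = np.array([xyz for _, _, _, xyz in spec], dtype=float)
    return Conformer(atoms, coords, model_id)


def make_hh_ensemble(distances_per_member):
    """Tiny ensembles of two amide protons at controlled separations.

    ``distances_per_member`` is a list of separations in Å; member m places
    residue 1 H at the origin and residue 2 H on the x axis.
    """
    members = []
    for m, d in enumerate(distances_per_member, start=1):
        members.append(
            make_conformer(
                [
                    (1, "ALA", "H", (0.0, 0.0, 0.0)),
                    (2, "ALA", "H", (d, 0.0, 0.0)),
                ],
                model_id=m,
            )
        )
    return ConformerEnsemble(members, label="toy")


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
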