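import numpy as np
import pytest

from react3d.reaction_io import Molecule3D, ReactionRecord
from react3d.synthetic_fixtures import SyntheticSpec, make_synthetic_reactions


@pytest.fixture(scope="session")
def small_reactions():
    """A small synthetic reaction set shared across tests."""
    spec = SyntheticSpec(n_reactions=12, sigma=0.0, seed=42)
    records, truth, ftable = make_synthetic_reactions(spec)
    return records, truth, ftable


@pytest.fixture
def water():
    """Water at (approximately) its equilibrium geometry."""
    return Molecule3D(
        elements=["O", "H", "H"],
        coords=np.array([[0.0, 0.0, 0.0],
                         [0.9572, 0.0, 0.0],
                         [-0.2399872, 0.9266272, 0.0]]))


@pytest.fixture
def identity_reaction(small_reactions):
    """A reaction whose product side is the reactant side verbatim."""
    rec = small_reactions[0][0]
    return ReactionRecord(
        id="identity",
        reactants=rec.reactants,
        products=[Molecule3D(list(m.elements), m.coords.copy())
                  for m in rec.reactants],
        regime="True",
        atom_map=np.arange(rec.n_reactant_atoms),
        target=0.0)


def rigid_motion(rng):
    """A random proper rotation + translation pair."""
    from react3d import so3
    return so3.random_rotation(rng), rng.normal(size=3) * 5.0


def transform_record(rec, rng):
    """Apply independent rigid motions to every molecule of a reaction."""
    import copy
    out = copy.deepcopy(rec)
    for m in out.reactants + out.products:
        R, t = rigid_motion(rng)
        m.coords = m.coords @ R.T + t
    return out
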