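import numpy as np
import pytest

from redoxmap import fixtures
from redoxmap.structures import Structure, AtomRecord


def brute_force_min_distance(coords_a, coords_b):
    """Exhaustive pairwise minimum distance, the distance oracle."""
    best = float("inf")
    for p in coords_a:
        for q in coords_b:
            best = min(best, float(np.linalg.norm(np.asarray(p) - np.asarray(q))))
    return best


def single_atom_cofactor(label, position, kind="FES"):
    """A one-atom cofactor instance for analytic distance tests."""
    from redoxmap.structures import CofactorInstance
    a = AtomRecord(serial=1, name="FE1", element="FE", altloc="", residue_name="FES",
                   chain_id=label[0] if label else "Z", residue_seq=900,
                   insertion_code="", position=np.asarray(position, float), is_hetero=True)
    return CofactorInstance(kind=kind, label=label, chain_id=a.chain_id,
                            residue_seq=900, atoms=[a], edge_atoms=[a])


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    from scipy.stats import special_ortho_group
    R = special_ortho_group.rvs(3, random_state=rng)
    t = rng.uniform(-20, 20, 3)
    return R, t


@pytest.fixture
def flavin_pair():
    return fixtures.make_flavin_pair(5.7)


@pytest.fixture
def hinge_pair():
    return fixtures.make_hinge_pair(26.0)


@pytest.fixture
def na_site():
    return fixtures.make_ion_site("NA", 5, 2.4,
                                  ligand_classes=["carbonyl"] * 3 + ["water"] * 2)


@pytest.fixture
def two_ring_channel():
    # ring-of-atoms radii 5.0 and 3.0 Å of carbon (vdW 1.70) => pore radii 3.30, 1.30
    return fixtures.make_channel([(0.0, 5.0 - 1.70), (8.0, 3.0 - 1.70)])
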