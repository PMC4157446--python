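import gemmi
import numpy as np
import pytest

from flexref.model_io import AtomicModel, ReflectionSet, full_sphere_hkl
from flexref.synthetic import ToySystemSpec, make_search_model, make_target, simulate_reflections


@pytest.fixture(scope="session")
def toy_spec():
    return ToySystemSpec(seed=1)


@pytest.fixture(scope="session")
def toy_target(toy_spec):
    return make_target(toy_spec)


@pytest.fixture(scope="session")
def toy_search(toy_spec, toy_target):
    model, bb_rmsd = make_search_model(toy_target, toy_spec)
    return model, bb_rmsd


@pytest.fixture(scope="session")
def toy_reflections(toy_spec, toy_target):
    return simulate_reflections(toy_target, toy_spec)


@pytest.fixture(scope="session")
def mini_spec():
    """A smaller, faster system for unit-level checks."""
    return ToySystemSpec(n_residues=6, seed=2, padding=8.0)


@pytest.fixture(scope="session")
def mini_target(mini_spec):
    return make_target(mini_spec)


def random_p1_model(n=20, cell_lengths=(20.0, 24.0, 18.0), b=15.0, seed=1):
    """A random few-atom P1 model for scattering tests."""
    rng = np.random.default_rng(seed)
    cell = gemmi.UnitCell(*cell_lengths, 90, 90, 90)
    els = ["C", "N", "O", "S"]
    return AtomicModel(
        serial=np.arange(1, n + 1),
        name=[f"X{i}" for i in range(n)],
        element=[els[i % 4] for i in range(n)],
        res_name=["UNK"] * n,
        res_num=np.arange(1, n + 1),
        chain=["A"] * n,
        icode=[""] * n,
        altloc=[""] * n,
        xyz=rng.random((n, 3)) * np.array(cell_lengths),
        occ=np.ones(n),
        b_iso=np.full(n, b),
        cell=cell,
    )


def reflections_for(model, d_min):
    hkl = full_sphere_hkl(model.cell, d_min)
    return ReflectionSet(hkl=hkl, f_obs=np.zeros(len(hkl)), cell=model.cell,
                         spacegroup=model.spacegroup)
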