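import numpy as np
import pytest

from desolvscan import (
    Ensemble,
    FixtureSpec,
    GBModelParams,
    NonpolarParams,
    SystemTopology,
    make_pseudo_trajectory,
    make_toy_complex,
)
from desolvscan.topology import AtomSpec


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=7, n_frames=5)


@pytest.fixture(scope="session")
def toy_top(default_spec):
    return make_toy_complex(default_spec)


@pytest.fixture(scope="session")
def toy_ens(default_spec, toy_top):
    return make_pseudo_trajectory(toy_top, default_spec)


@pytest.fixture(scope="session")
def base_ens(toy_top):
    """Single noise-free frame of the toy complex."""
    return Ensemble(toy_top, toy_top.positions[None], [0.0])


@pytest.fixture(scope="session")
def params():
    return GBModelParams(model="OBC2")


@pytest.fixture(scope="session")
def nonpolar():
    return NonpolarParams()


def micro_atom(atom_id, name, residue_key, pos, charge, gb_radius=1.6,
               gb_screen=0.8, rmin_half=1.9, eps=0.1):
    return AtomSpec(
        atom_id=atom_id, name=name, element=name[0], residue_key=residue_key,
        position=np.asarray(pos, dtype=float), charge=charge,
        gb_radius=gb_radius, gb_screen=gb_screen,
        lj_rmin_half=rmin_half, lj_epsilon=eps,
    )


@pytest.fixture(scope="session")
def tiny_complex():
    """Diatomic receptor + monatomic ligand for brute-force oracles."""
    atoms = [
        micro_atom(0, "CA", ("A", 1, "R1"), [0.0, 0.0, 0.0], 0.50, 1.5),
        micro_atom(1, "CB", ("A", 1, "R1"), [1.5, 0.0, 0.0], -0.30, 1.7),
        micro_atom(2, "CA", ("B", 1, "L1"), [0.7, 3.2, 0.0], -0.20, 1.6),
    ]
    return SystemTopology(atoms, {"A"}, {"B"})
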