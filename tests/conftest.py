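import numpy as np
import pytest

from hatforge import (
    Conformer,
    NMSParams,
    ToyPotential,
    finite_difference_hessian,
    normal_modes,
)
from hatforge.geometry import Geometry
from hatforge.molecules import embed_with_topology, optimize_geometry
from hatforge.fixtures import make_two_well_hat_system


@pytest.fixture(scope="session")
def glycine():
    """Embedded uncapped glycine with its bond list."""
    geom, bonds, _ = embed_with_topology("NCC(=O)O", seed=0)
    return geom, bonds


@pytest.fixture(scope="session")
def optimized_glycine(glycine):
    """Glycine relaxed on its own toy surface, with Hessian normal modes."""
    geom, bonds = glycine
    calc = ToyPotential(geom, bonds)
    opt = optimize_geometry(geom, calc, gradient_tolerance=1e-4, max_steps=1000)
    assert opt.converged
    hess = finite_difference_hessian(opt.geometry, calc)
    modes = normal_modes(hess, opt.geometry.masses, opt.geometry)
    return opt.geometry, bonds, calc, modes


@pytest.fixture(scope="session")
def two_well():
    """The collinear double-well HAT fixture and its calculator."""
    return make_two_well_hat_system()


@pytest.fixture()
def diatomic():
    """Harmonic C–C diatomic at 1.5 Å equilibrium, spring k=5 eV/Å²."""
    ref = Geometry(["C", "C"], [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
    calc = ToyPotential(ref, [(0, 1)], bond_k=5.0)
    return ref, calc


def toy_conformer(geometry) -> Conformer:
    return Conformer(geometry, 0.0, "test")
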