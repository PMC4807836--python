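import numpy as np
import pytest

from vibro import ToySpec, compute_normal_modes, make_toy_molecule


@pytest.fixture
def diatomic():
    """Homonuclear-mass diatomic with charges +/-0.3 e and its exact Hessian."""
    spec = ToySpec(topology="diatomic", masses=[2.0, 2.0], k_bond=0.25,
                   charges=[0.3, -0.3])
    mol, hess, truth = make_toy_molecule(spec)
    return mol, hess, truth


@pytest.fixture
def bent_triatomic():
    spec = ToySpec(topology="bent_triatomic", masses=[1.0, 16.0, 1.0],
                   k_bond=0.35, k_bend=0.1)
    mol, hess, truth = make_toy_molecule(spec)
    return mol, hess, truth


@pytest.fixture
def bent_modes(bent_triatomic):
    mol, hess, truth = bent_triatomic
    return mol, hess, compute_normal_modes(hess)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
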