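import numpy as np
import pytest

import qsar3d as q


@pytest.fixture(scope="session")
def reference_records():
    return q.load_reference_table()


@pytest.fixture(scope="session")
def toy_molecule():
    """5-atom rigid fragment with mixed elements and charges."""
    atoms = [
        q.Atom("C", [0.0, 0.0, 0.0], partial_charge=0.10),
        q.Atom("N", [1.4, 0.2, 0.1], partial_charge=-0.35),
        q.Atom("O", [-0.8, 1.1, -0.4], partial_charge=-0.42),
        q.Atom("H", [2.1, -0.6, 0.3], partial_charge=0.20),
        q.Atom("Cl", [0.3, -1.6, 1.0], partial_charge=-0.08),
    ]
    return q.Molecule("toy", atoms, core_atom_indices=[0, 1, 2])


@pytest.fixture(scope="session")
def noisy_series():
    """Default synthetic study conditions (40 molecules, noise 0.1)."""
    spec = q.SyntheticSpec(seed=11)
    molecules, activities, weights = q.generate_series(spec)
    block = q.series_block(spec, molecules)
    return spec, molecules, activities, weights, block


@pytest.fixture(scope="session")
def noiseless_series():
    spec = q.SyntheticSpec(seed=11, noise_sd=0.0)
    molecules, activities, weights = q.generate_series(spec)
    block = q.series_block(spec, molecules)
    return spec, molecules, activities, weights, block


@pytest.fixture(scope="session")
def small_matrix():
    """Random 8x5 regression problem with real signal."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(8, 5))
    beta = np.array([1.5, -2.0, 0.0, 0.7, 0.0])
    y = X @ beta + rng.normal(scale=0.3, size=8)
    return X, y
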