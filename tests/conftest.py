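import numpy as np
import pytest

import funcarto as fc


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_clique_slice():
    """One slice: two disconnected 4-cliques of unit weight."""
    A = np.zeros((8, 8))
    A[:4, :4] = 1.0
    A[4:, 4:] = 1.0
    np.fill_diagonal(A, 0.0)
    return A


@pytest.fixture
def clean_planted():
    """Noise-free planted scenario: 2 systems x 4 nodes, 3 slices."""
    scenario = fc.PlantedScenario.uniform(
        2, 4, 3, flip_prob=0.0, mu_in=1.0, mu_out=0.0, sigma=0.0, seed=0
    )
    net, truth = fc.generate_planted_multilayer(scenario, omega=0.5)
    return scenario, net, truth


@pytest.fixture
def noisy_planted():
    """Noisy planted scenario: 4 systems x 8 nodes, 8 slices, 10% flips."""
    scenario = fc.PlantedScenario.uniform(
        4, 8, 8, flip_prob=0.1, mu_in=0.8, mu_out=0.2, sigma=0.1, seed=7
    )
    net, truth = fc.generate_planted_multilayer(scenario)
    return scenario, net, truth


@pytest.fixture
def small_ensemble(noisy_planted):
    _, net, _ = noisy_planted
    return fc.run_ensemble(net, n_runs=8, seed=3)
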