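import numpy as np
import pytest
from hypothesis import settings

from devhourglass import (
    EvolutionParams,
    Genome,
    SimulationParams,
    make_fixture,
    random_genome,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A 6-gene, 8-cell instance: 2 morphogens + 4 markers, no spare genes."""
    return SimulationParams(n_genes=6, n_cells=8, n_steps=50)


@pytest.fixture
def toy_params():
    """An 8-gene, 16-cell instance with two free (non-marker) genes."""
    return SimulationParams(n_genes=8, n_cells=16, n_steps=100)


@pytest.fixture
def toy_evo():
    return EvolutionParams(pop_size=10, n_generations=5)


@pytest.fixture
def toy_genome(toy_params, rng):
    return random_genome(toy_params, rng)


@pytest.fixture
def chain():
    return make_fixture("chain")


@pytest.fixture
def bistable():
    return make_fixture("bistable-switch")


def naive_step(field, genome, params):
    """Reference stepper: explicit per-cell, per-gene loops.

    Independent of the vectorized implementation; used as the oracle for
    stepper equivalence.
    """
    N, L = field.shape
    morph = set(params.morphogen_indices)
    new = field.copy()
    for i in range(N):
        if i in morph:
            continue
        for l in range(L):
            s = 0.0
            for j in range(N):
                s += genome.interactions[i, j] * field[j, l]
            F = 1.0 / (1.0 + np.exp(-params.beta * (s - genome.theta[i])))
            left = field[i, l - 1] if l > 0 else field[i, 0]
            right = field[i, l + 1] if l < L - 1 else field[i, L - 1]
            lap = left - 2.0 * field[i, l] + right
            new[i, l] = field[i, l] + params.dt * (
                genome.gamma[i] * (F - field[i, l])
                + genome.diffusion[i] * lap
            )
    return new


def constant_genome(params, *, gamma=1.0, theta=0.0, diffusion=0.0, x_init=0.0):
    """All-zero interaction matrix with uniform scalar parameters."""
    N = params.n_genes
    return Genome(
        interactions=np.zeros((N, N), dtype=np.int8),
        gamma=np.full(N, float(gamma)),
        theta=np.full(N, float(theta)),
        diffusion=np.full(N, float(diffusion)),
        x_init=np.full(N, float(x_init)),
    )
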