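import numpy as np
import pytest

from phlinkage.model import SiteModel, build_dimer_model
from phlinkage.sampling import sample_ensemble
from phlinkage.testsystems import (GLU_WATER_PKA, coupled_pair, toy_dimer,
                                   toy_flip_probs, toy_monomer,
                                   uncoupled_single_site)


@pytest.fixture(scope="session")
def single_site():
    return uncoupled_single_site(GLU_WATER_PKA)


@pytest.fixture(scope="session")
def anticooperative_pair():
    """Two sites penalized for simultaneous protonation (+2 kcal/mol)."""
    return coupled_pair(4.0, 5.0, +2.0)


@pytest.fixture(scope="session")
def mixed_six_site():
    """Six sites with mixed positive/negative couplings, enumerable exactly."""
    w = np.zeros((6, 6))
    w[0, 1] = w[1, 0] = +1.5
    w[2, 3] = w[3, 2] = -2.0
    w[1, 4] = w[4, 1] = -0.8
    return SiteModel(
        pka_int=[4.2, 4.8, 5.3, 5.9, 6.4, 4.5],
        coupling=w,
        labels=tuple(f"s{i}" for i in range(6)),
        chain=("M",) * 6,
        compartment=("lumenal",) * 3 + ("stromal",) * 3,
    )


@pytest.fixture(scope="session")
def toy_models():
    monomer = toy_monomer()
    return monomer, toy_dimer(monomer)


@pytest.fixture(scope="session")
def small_grid():
    return np.round(np.arange(3.0, 8.0 + 1e-9, 0.5), 10)


@pytest.fixture(scope="session")
def sampled_pair_ensemble(anticooperative_pair, small_grid):
    return sample_ensemble(anticooperative_pair, small_grid, n_replicates=4,
                           n_frames=20_000, seed=7)


@pytest.fixture(scope="session")
def toy_sampled(toy_models):
    """Reduced-size sampled toy ensembles shared across analysis tests."""
    monomer, dimer = toy_models
    grid = np.round(np.arange(3.0, 8.0 + 1e-9, 0.5), 10)
    mon = sample_ensemble(monomer, grid, n_replicates=4, n_frames=20_000,
                          seed=11, flip_attempt_prob=toy_flip_probs(monomer),
                          system="monomer")
    dim = sample_ensemble(dimer, grid, n_replicates=4, n_frames=20_000,
                          seed=12, flip_attempt_prob=toy_flip_probs(dimer),
                          system="dimer")
    return mon, dim


@pytest.fixture(scope="session")
def independent_copy_dimer():
    """Monomer plus a dimer that is two strictly independent copies of it."""
    monomer = SiteModel(
        pka_int=[4.1, 5.2, 6.0],
        coupling=np.zeros((3, 3)),
        labels=("a", "b", "c"),
        chain=("M",) * 3,
        compartment=("lumenal", "lumenal", "stromal"),
    )
    dimer = build_dimer_model(monomer)
    return monomer, dimer
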