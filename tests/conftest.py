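import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cagsim import make_synthetic_schedule, preset, run_ensemble
from cagsim.fertility import load_fertility_schedule

# master seeds for the multi-seed ensemble fixtures (fixed, arbitrary)
ENSEMBLE_SEEDS = (0, 1, 2, 3, 4)
N_LINEAGES = 1000


@pytest.fixture(scope="session")
def schedule():
    """Packaged synthetic fertility schedule (peak 30 y, spread 6 y)."""
    return make_synthetic_schedule()


@pytest.fixture(scope="session")
def uniform_schedule():
    """Flat fertility density over the 12-50 window (closed-form oracle)."""
    ages = np.arange(12, 51, dtype=float)
    return load_fertility_schedule(np.column_stack([ages, np.ones_like(ages)]))


@pytest.fixture(scope="session")
def sca2():
    return preset("sca2")


@pytest.fixture(scope="session")
def sca3():
    return preset("sca3")


def _multi_seed(cfg, schedule):
    runs = []
    for seed in ENSEMBLE_SEEDS:
        outcomes, summary = run_ensemble(cfg, schedule, N_LINEAGES, seed)
        runs.append((outcomes, summary))
    return runs


@pytest.fixture(scope="session")
def sca2_runs(sca2, schedule):
    """Five independent 1,000-lineage SCA2 ensembles."""
    return _multi_seed(sca2, schedule)


@pytest.fixture(scope="session")
def sca3_runs(sca3, schedule):
    """Five independent 1,000-lineage SCA3 ensembles."""
    return _multi_seed(sca3, schedule)
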