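import numpy as np
import pytest

from gatecycle.simulate import default_study_conditions, generate_tmca_study


@pytest.fixture(scope="session")
def tiny_coupled_study():
    """A small four-corner study (< 1 MB on disk) with a 3 kT coupling."""
    return generate_tmca_study(
        default_study_conditions("coupled"), replicates=3, n_samples=400, seed=7
    )


@pytest.fixture(scope="session")
def small_coupled_study():
    """A mid-sized coupled study good enough for quantitative recovery."""
    return generate_tmca_study(
        default_study_conditions("coupled"), replicates=6, n_samples=2000, seed=11
    )


@pytest.fixture(scope="session")
def incomplete_study():
    """Study whose mutant cannot be activated by the alternative ligand.

    Sampled finely enough (2000 samples/sweep) for the mutant's
    noise-analysis anchor to be reliable on the corners that do activate.
    """
    return generate_tmca_study(
        default_study_conditions("incomplete"), replicates=4, n_samples=2000, seed=13
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
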