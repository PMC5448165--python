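import numpy as np
import pytest

from erk_decode import (build_empirical_null, sample_gene_params,
                        simulate_experiment)


@pytest.fixture(scope="session")
def small_truth():
    return sample_gene_params(
        {"IEG": 8, "ILG": 8, "DEG": 8, "uninduced": 176}, seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    matrix, truth_df = simulate_experiment(small_truth, seed=102)
    return matrix, truth_df


@pytest.fixture(scope="session")
def small_null(small_dataset):
    matrix, _ = small_dataset
    with pytest.warns(UserWarning, match="shrunk"):
        return build_empirical_null(matrix, "ON", time=120.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170503)
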