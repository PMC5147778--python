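import numpy as np
import pytest

from popdim import (gratings_movie, noise_movie, pca_patterns,
                    preprocess_movie)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gratings_matrix():
    """Preprocessed full-scale gratings movie (expensive; shared)."""
    return preprocess_movie(gratings_movie(rng_seed=1))


@pytest.fixture(scope="session")
def noise_matrix():
    return preprocess_movie(noise_movie(rng_seed=1))


@pytest.fixture(scope="session")
def gratings_patterns(gratings_matrix):
    return pca_patterns(gratings_matrix, 0.9)


@pytest.fixture(scope="session")
def noise_patterns(noise_matrix):
    return pca_patterns(noise_matrix, 0.9)
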