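import numpy as np
import pytest

from callcensus import cluster as cl
from callcensus.pipeline_io import build_clear_corpus
from callcensus.synth import sample_population


def build_corpus(seed, n_individuals, calls_per_individual, snr_db=20.0):
    """Sample a population and curate a clear-call corpus from it.

    Returns (cut spectrograms, labels, measurements, profiles); mirrors
    field practice where only clear calls enter the analysis.
    """
    rng = np.random.default_rng(seed)
    profiles = sample_population(n_individuals, seed=rng)
    specs, measurements, labels = build_clear_corpus(
        profiles, calls_per_individual, snr_db=snr_db, seed=rng
    )
    return specs, labels, measurements, profiles


@pytest.fixture(scope="session")
def small_corpus():
    """8 individuals x 5 calls at 20 dB SNR, with SPCC similarity matrix."""
    specs, labels, measurements, profiles = build_corpus(123, 8, 5)
    matrix = cl.similarity_matrix(specs)
    return {
        "specs": specs,
        "labels": np.array(labels),
        "measurements": measurements,
        "profiles": profiles,
        "matrix": matrix,
    }
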