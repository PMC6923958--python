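import numpy as np
import pytest
from hypothesis import settings

from stressgenepred import SyntheticConfig, TimeSeriesSample, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_sample(series_by_gene, sample_id="s1", stress="cold", replicates=1):
    """Build a TimeSeriesSample from a list of per-gene mean series.

    Each series is replicated `replicates` times so replicate averaging is
    the identity on the intended means.
    """
    arr = np.asarray(series_by_gene, dtype=float)[:, :, None]
    arr = np.repeat(arr, replicates, axis=2)
    return TimeSeriesSample(sample_id=sample_id, stress=stress, values=arr)


@pytest.fixture
def toy_sample():
    """3 genes x 3 time points: one up, one down, one flat."""
    return make_sample(
        [[10.0, 26.0, 7.0], [8.0, 4.0, 8.0], [5.0, 5.0, 5.0]],
        sample_id="toy",
        stress="heat",
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced synthetic corpus shared by expensive tests."""
    cfg = SyntheticConfig(
        n_genes=300,
        samples_per_stress=(10, 9, 7, 4),
        specific_genes_per_stress=12,
        shared_gene_pairs=4,
        seed=7,
    )
    samples, truth = generate_dataset(cfg)
    return cfg, samples, truth
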