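import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_dataset():
    """No-admixture, no-migration genome at the default desk scale
    (2 x 10 Mb, 10 diploids/taxon): shared by the calibration tests."""
    from hhscan.core import allele_frequencies, iter_windows
    from hhscan.simulate import default_layout, default_model, simulate_dataset

    model = default_model(H=0.0)
    layout = default_layout()
    matrix, meta, truth = simulate_dataset(model, layout, seed=2024)
    freqs = allele_frequencies(matrix, meta, min_alleles=20)
    windows = iter_windows(matrix.contig_lengths, 100_000)
    return matrix, meta, freqs, windows, truth


@pytest.fixture(scope="session")
def admixed_dataset():
    """H = 0.25 pulse genome (1 x 10 Mb) without continuous migration."""
    from hhscan.core import allele_frequencies, iter_windows
    from hhscan.simulate import default_layout, default_model, simulate_dataset

    model = default_model(H=0.25)
    layout = default_layout(n_contigs=1)
    matrix, meta, truth = simulate_dataset(model, layout, seed=777)
    freqs = allele_frequencies(matrix, meta, min_alleles=20)
    windows = iter_windows(matrix.contig_lengths, 100_000)
    return matrix, meta, freqs, windows, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
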