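import pandas as pd
import pytest

from xtissue import SyntheticConfig, generate_tissue_profiles, sample_read_counts


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small four-tissue study; quick enough for every stage."""
    return SyntheticConfig(
        seed=7,
        n_genes=600,
        n_enriched_per_tissue=30,
        total_reads_per_tissue=2_000_000,
    )


@pytest.fixture(scope="session")
def small_profiles(small_config):
    return generate_tissue_profiles(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_profiles):
    matrix, _ = small_profiles
    return sample_read_counts(matrix, small_config)


@pytest.fixture()
def tiny_matrix() -> pd.DataFrame:
    """Hand-sized cluster-by-tissue matrix for exact-value checks."""
    return pd.DataFrame(
        {
            "swimbladder": [500.0, 20.0, 5.0, 28.0, 300.0],
            "brain": [10.0, 10.0, 1.0, 0.0, 290.0],
            "heart": [20.0, 20.0, 1.5, 0.0, 310.0],
            "kidney": [30.0, 30.0, 0.5, 0.0, 305.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD", "gE"], name="cluster"),
    )
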