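import numpy as np
import pandas as pd
import pytest

from phylloload import FeatureTable, GeneratorConfig, SampleMetadata, generate


@pytest.fixture
def small_table() -> FeatureTable:
    df = pd.DataFrame(
        [[10, 5], [30, 15], [60, 80]],
        index=pd.Index(["FamA", "FamB", "FamC"], name="taxon"),
        columns=["s1", "s2"],
    )
    return FeatureTable(df, "raw_counts")


@pytest.fixture
def small_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {"plant_reads": [100, 200], "site": ["EY", "JUG"]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def desk_config() -> GeneratorConfig:
    """Small, fast study conditions for unit-level simulation tests."""
    return GeneratorConfig(
        n_samples=40, total_depth=200_000, amplicon_depth=5_000, seed=0
    )


@pytest.fixture(scope="session")
def desk_dataset(desk_config):
    return generate(desk_config, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the full default study conditions (150 samples, 15M reads)."""
    return generate(GeneratorConfig(), seed=7)


def random_count_table(rng: np.random.Generator, n_taxa=6, n_samples=5) -> FeatureTable:
    counts = rng.integers(0, 500, size=(n_taxa, n_samples))
    counts[0] += 1  # keep every column non-empty
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"T{i}" for i in range(n_taxa)], name="taxon"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return FeatureTable(df, "raw_counts")
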