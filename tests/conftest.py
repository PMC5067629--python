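import numpy as np
import pandas as pd
import pytest

from xplatclust import ExpressionMatrix, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Clean, well-separated 4-cluster dataset with modest noise."""
    cfg = SimConfig(
        n_clusters=4,
        genes_per_cluster=30,
        profile_noise_sd=0.15,
        replication_fraction=1.0,
        n_enriched_classes=2,
        enrichment_factor=6.0,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Noise-free dataset: profiles equal archetypes, counts are rounded means."""
    cfg = SimConfig(
        n_clusters=3,
        genes_per_cluster=20,
        profile_noise_sd=0.0,
        array_noise_sd=0.0,
        nb_dispersion=0.0,
        deterministic_counts=True,
        replication_fraction=1.0,
        baseline_mean_log10=(3.0, 4.0),
        seed=7,
    )
    return cfg, simulate_dataset(cfg)


def make_expression(values, columns, platform="array", genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=columns)
    return ExpressionMatrix(values=df, platform=platform)


@pytest.fixture
def tiny_array():
    return make_expression(
        [[10, 20, 40], [8, 8, 8]], ["t0_r1", "t4_r1", "t8_r1"], platform="array"
    )
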