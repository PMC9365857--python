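import numpy as np
import pandas as pd
import pytest

from tuftnet.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit tests: 6 samples, 400 genes, 5 clusters."""
    cfg = SimConfig(
        n_samples=6,
        n_genes=400,
        n_clusters=5,
        rare_cluster_index=4,
        cells_per_sample=250,
        target_module=[f"MOD{i + 1:03d}" for i in range(30)],
        rare_fraction=0.03,
        seed=42,
    )
    adata, truth = generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the reference study conditions."""
    cfg = SimConfig(seed=7)
    adata, truth = generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_counts(n_samples=4, n_genes=6, seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 50, size=(n_samples, n_genes))
    return pd.DataFrame(counts, index=[f"S{i}" for i in range(n_samples)],
                        columns=[f"g{j}" for j in range(n_genes)])
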