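import numpy as np
import pandas as pd
import pytest

from sdegkit import GeneSetCollection, SimConfig, simulate_de_table


@pytest.fixture
def de_table_small():
    """A 6-gene DE table with hand-picked values spanning both directions."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "base_mean": [100.0, 50.0, 10.0, 400.0, 30.0, 5.0],
            "log2FoldChange": [2.0, -0.4941, 0.0, 3.0, -1.5, 0.1],
            "pvalue": [1e-4, 1e-9, 0.5, 1e-6, 1e-3, 0.8],
            "padj": [1e-3, 1.01e-8, 0.9, 1e-5, 5e-3, 0.95],
            "stat": [4.0, -6.0, 0.1, 5.0, -3.0, 0.2],
        }
    )


@pytest.fixture
def planted_bundle():
    """Seeded synthetic DE table + truth with planted up/down components."""
    config = SimConfig(seed=42, n_genes=2000)
    de_table, truth = simulate_de_table(config)
    return config, de_table, truth


@pytest.fixture
def toy_collection():
    bg = [f"g{i}" for i in range(20)]
    return GeneSetCollection(
        sets={"first_five": bg[:5], "last_four": bg[16:], "mixed": bg[3:9]},
        descriptions={"first_five": "toy"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
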