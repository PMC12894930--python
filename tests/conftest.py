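import numpy as np
import pandas as pd
import pytest

from proxiscore import SimulationConfig, make_ground_truth
from proxiscore.display import AMINO_ACIDS, POSITIONS


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions for fast unit tests."""
    return SimulationConfig(
        n_proteins=200, n_interactors=10, n_reads_input=5000,
        n_reads_selected=5000, n_sites=50, seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_ground_truth(small_config)


@pytest.fixture
def random_matrix_frame():
    """Factory for random 20x11 enrichment-matrix DataFrames."""

    def _make(seed: int, scale: float = 1.0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        values = rng.normal(0.0, scale, size=(20, 11))
        values[:, 5] = 0.0  # fixed central Y column
        return pd.DataFrame(values, index=list(AMINO_ACIDS), columns=list(POSITIONS))

    return _make


def make_enrichment_table(rng, n=20, hit_frac=0.3):
    """Random per-protein enrichment table for set-operation tests."""
    ids = [f"P{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "log2_fc": rng.normal(0.5, 1.2, size=n),
            "p_value": rng.random(n),
        },
        index=pd.Index(ids, name="protein_id"),
    )
    table["hit"] = (table["p_value"] < 0.05) & (table["log2_fc"] > 1.0)
    # force a few hits so overlaps are non-trivial
    force = rng.choice(n, size=max(1, int(hit_frac * n)), replace=False)
    table.iloc[force, table.columns.get_loc("p_value")] = rng.random(len(force)) * 0.04
    table.iloc[force, table.columns.get_loc("log2_fc")] = 1.0 + rng.random(len(force)) * 2
    table["hit"] = (table["p_value"] < 0.05) & (table["log2_fc"] > 1.0)
    return table
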