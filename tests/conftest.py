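import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy import sparse

from nichestat.dataset import SpatialDataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def build_dataset(
    counts,
    coords=None,
    sample_ids=None,
    conditions=None,
    genes=None,
    cell_ids=None,
    norm=None,
):
    """Assemble a small SpatialDataset from plain arrays/lists."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    coords = np.asarray(coords if coords is not None else np.zeros((n_cells, 2)), float)
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids or [f"c{i}" for i in range(n_cells)],
            "x_um": coords[:, 0],
            "y_um": coords[:, 1],
            "sample_id": sample_ids or ["s1"] * n_cells,
            "condition": conditions or ["control"] * n_cells,
        }
    )
    ds = SpatialDataset(
        cells=cells,
        genes=genes or [f"g{i}" for i in range(n_genes)],
        counts=sparse.csc_matrix(counts),
    )
    if norm is not None:
        ds.norm = sparse.csc_matrix(np.asarray(norm, float))
    return ds


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic desk-scale simulated study shared across tests."""
    from nichestat.synthetic import simulate, small_config

    return simulate(small_config(seed=1))
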