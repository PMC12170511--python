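import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hexniche import SyntheticConfig, generate_grid, plant_truth, simulate_counts
from hexniche.spatial_io import CountMatrix, SpotGrid


def make_grid(n_rows=6, n_cols=6, slide="s1", benign_rows=0):
    """Full single-slide hex grid with an optional benign top band."""
    rows = []
    for r in range(n_rows):
        for j in range(n_cols):
            c = 2 * j + (r % 2)
            region = "benign" if r < benign_rows else "tumor"
            rows.append((f"{slide}_{r}_{c}", slide, r, c, True, region))
    df = pd.DataFrame(
        rows, columns=["barcode", "slide_id", "array_row", "array_col", "in_tissue", "region"]
    ).set_index("barcode")
    return SpotGrid(df)


def random_counts(n_genes=20, n_spots=12, density=0.5, seed=0, max_count=40):
    rng = np.random.default_rng(seed)
    dense = rng.integers(1, max_count, size=(n_genes, n_spots))
    dense *= rng.random((n_genes, n_spots)) < density
    # every spot needs a nonzero total for normalization
    dense[0, :] = np.maximum(dense[0, :], 1)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    spots = [f"spot{i:03d}" for i in range(n_spots)]
    return CountMatrix(genes, spots, sp.csr_matrix(dense))


@pytest.fixture
def toy_grid():
    return make_grid(6, 6)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(
        seed=0,
        n_rows=16,
        n_cols=16,
        n_genes=400,
        n_subclones=4,
        n_response_genes_tumor=30,
        n_response_genes_benign=10,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    grid = generate_grid(small_cfg)
    truth = plant_truth(grid, small_cfg)
    counts = simulate_counts(grid, truth, small_cfg, "deep")
    return grid, truth, counts
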