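import numpy as np
import pytest
import scipy.sparse as sp

from spatialshell import CellTable, ExpressionGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_grid(images: dict[str, np.ndarray], pitch: float = 10.0) -> ExpressionGrid:
    """Build an ExpressionGrid from dense per-gene count images (row, col)."""
    genes = list(images)
    shape = images[genes[0]].shape
    n_rows, n_cols = shape
    mat = np.stack([images[g].reshape(-1) for g in genes], axis=1)
    return ExpressionGrid(
        pitch=pitch,
        n_cols=n_cols,
        n_rows=n_rows,
        origin=(0.0, 0.0),
        counts=sp.csr_matrix(mat),
        gene_names=genes,
    )


def make_cells(x, y, counts, genes=None) -> CellTable:
    counts = np.atleast_2d(np.asarray(counts))
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    return CellTable(
        cell_ids=np.array([f"c{i}" for i in range(len(x))], dtype=object),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        counts=sp.csr_matrix(counts),
        gene_names=genes,
    )


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def cell_factory():
    return make_cells
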