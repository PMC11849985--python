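"""Domain-level pseudobulk profiles, alpha diversity and spatial autocorrelation.

Each spatial domain is summarised as a pseudobulk profile: the mean per-grid
count of every gene over the domain's grids.  Profiles are the unit for the
clustering/trajectory stage and for diversity comparisons against single
cells.  Alpha-diversity estimators delegate to scikit-bio; Geary's C is
computed directly from its definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skbio.diversity import alpha as _alpha

from .detect import DomainLabeling
from .grid_io import ExpressionGrid

__all__ = [
    "DomainProfiles",
    "domain_expression",
    "chao1",
    "shannon",
    "observed_features",
    "gearys_c",
    "mask_adjacency",
]


@dataclass
class DomainProfiles:
    """Domain x gene mean-count matrix plus per-domain metadata.

    ``expression`` is indexed by domain id; ``meta`` shares that index and
    carries area, centroid, provenance (sample/patient) and, once computed,
    cluster labels and pseudotime.
    """

    expression: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.meta.index):
            raise ValueError("expression and meta must share their index")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("mean expression values cannot be negative")

    @property
    def n_domains(self) -> int:
        return len(self.expression)

    @property
    def gene_names(self) -> list[str]:
        return list(self.expression.columns)


def domain_expression(
    grid: ExpressionGrid,
    labeling: DomainLabeling,
    sample_id: str | None = None,
    patient_id: str | None = None,
) -> DomainProfiles:
    """Average the grid counts of every gene within each spatial domain."""
    if labeling.labels.shape != grid.shape:
        raise ValueError("labeling must be aligned to the grid lattice")
    n = labeling.n_domains
    flat_labels = labeling.labels.ravel()
    rows = []
    for d in range(1, n + 1):
        idx = np.flatnonzero(flat_labels == d)
        rows.append(np.asarray(grid.counts[idx].mean(axis=0)).ravel())
    expression = pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, grid.n_genes)),
        index=pd.Index(np.arange(1, n + 1), name="domain_id"),
        columns=grid.gene_names,
    )
    meta = pd.DataFrame(
        {
            "area": labeling.areas,
            "centroid_col": labeling.centroids[:, 0] if n else np.zeros(0),
            "centroid_row": labeling.centroids[:, 1] if n else np.zeros(0),
        },
        index=expression.index,
    )
    if sample_id is not None:
        meta["sample_id"] = sample_id
    if patient_id is not None:
        meta["patient_id"] = patient_id
    return DomainProfiles(expression=expression, meta=meta)


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)) (bias-corrected form).

    F1/F2 are singleton/doubleton counts.  The classic F1^2/(2 F2) estimator
    is available with ``bias_corrected=False``.
    """
    counts = np.asarray(counts)
    if not counts.any():
        return 0.0
    return float(_alpha.chao1(counts, bias_corrected=bias_corrected))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of the count composition (bits by default)."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValueError("shannon entropy requires a positive total count")
    return float(_alpha.shannon(counts, base=base))


def observed_features(counts) -> int:
    """Number of features with a strictly positive count."""
    return int(_alpha.observed_features(np.asarray(counts)))


def mask_adjacency(mask: np.ndarray) -> sp.csr_matrix:
    """Binary 8-adjacency weights among the true grids of a mask.

    Row/column order follows the raster order of the true grids; use this as
    the default weight matrix for per-grid Geary's C within a region.
    """
    n_rows, n_cols = mask.shape
    order = np.full(mask.size, -1, dtype=int)
    flat = np.flatnonzero(mask.ravel())
    order[flat] = np.arange(flat.size)
    rows_idx, cols_idx = np.divmod(flat, n_cols)
    src, dst = [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        rr, cc = rows_idx + dr, cols_idx + dc
        ok = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
        neigh = order[rr[ok] * n_cols + cc[ok]]
        here = order[flat[ok]]
        keep = neigh >= 0
        src.append(here[keep])
        dst.append(neigh[keep])
    src = np.concatenate(src) if src else np.zeros(0, dtype=int)
    dst = np.concatenate(dst) if dst else np.zeros(0, dtype=int)
    w = sp.coo_matrix(
        (np.ones(src.size), (src, dst)), shape=(flat.size, flat.size)
    )
    return (w + w.T).tocsr()


def gearys_c(values, weights) -> float:
    """Geary's C spatial autocorrelation.

    C = (n-1) * sum_ij w_ij (x_i - x_j)^2 / (2 W sum_i (x_i - xbar)^2) with
    W the total weight.  Values below 1 indicate positive spatial
    autocorrelation.  ``weights`` is a symmetric (sparse or dense) matrix.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("Geary's C needs at least two spatial units")
    w = sp.csr_matrix(weights) if not sp.issparse(weights) else weights.tocsr()
    if w.shape != (n, n):
        raise ValueError("weights shape must match the number of units")
    total_w = w.sum()
    if total_w == 0:
        raise ValueError("weight matrix has no edges")
    ss = float(((x - x.mean()) ** 2).sum())
    if ss == 0:
        raise ValueError("constant field: Geary's C is undefined")
    coo = w.tocoo()
    num = float((coo.data * (x[coo.row] - x[coo.col]) ** 2).sum())
    return (n - 1) * num / (2.0 * total_w * ss)
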