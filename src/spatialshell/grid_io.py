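"""Load cell tables and count matrices and bin them onto a fixed-pitch lattice.

The in-situ platforms this package targets (Xenium-style output) deliver a
cell-by-gene count matrix (MatrixMarket triplet with gene/barcode index files,
or a delimited dense table) together with a cell table holding the x/y
centroid of every segmented cell in micrometres.  All downstream analysis
works on a square expression lattice: each cell's counts are accumulated into
the grid square containing its centroid (default pitch 10 µm, half-open bins
``[k*pitch, (k+1)*pitch)``).
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CellTable",
    "ExpressionGrid",
    "load_cells",
    "build_grid",
    "write_cells",
    "write_grid",
    "read_grid",
]


@dataclass
class CellTable:
    """One row per segmented cell: identifier, centroid (µm) and counts.

    ``counts`` is a CSR matrix of shape ``(n_cells, n_genes)`` aligned with
    ``gene_names``.
    """

    cell_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    counts: sp.csr_matrix
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        n = len(self.cell_ids)
        if not (len(self.x) == len(self.y) == n == self.counts.shape[0]):
            raise ValueError("cell_ids, coordinates and counts must agree in length")
        if self.counts.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length must match the count-matrix width")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell identifiers must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts are not allowed")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


@dataclass
class ExpressionGrid:
    """Per-grid, per-gene counts on a fixed-pitch lattice.

    Grids are addressed ``(col, row)`` with 0-based indices; ``origin`` is the
    µm coordinate of the lower-left corner of grid ``(0, 0)`` (the minimum
    cell coordinate rounded down to a pitch multiple).  Counts are stored as a
    CSR matrix of shape ``(n_rows * n_cols, n_genes)`` with flat index
    ``row * n_cols + col``.
    """

    pitch: float
    n_cols: int
    n_rows: int
    origin: tuple[float, float]
    counts: sp.csr_matrix
    gene_names: list[str]

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("lattice dimensions must be positive")
        self.counts = self.counts.tocsr()
        if self.counts.shape != (self.n_rows * self.n_cols, len(self.gene_names)):
            raise ValueError("counts shape must be (n_rows*n_cols, n_genes)")

    @property
    def shape(self) -> tuple[int, int]:
        """Lattice shape as ``(n_rows, n_cols)`` (numpy image convention)."""
        return (self.n_rows, self.n_cols)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def flat_index(self, col: np.ndarray, row: np.ndarray) -> np.ndarray:
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in panel: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def gene_image(self, gene: str) -> np.ndarray:
        """Dense ``(n_rows, n_cols)`` count image of a single gene."""
        j = self.gene_index([gene])[0]
        col = np.asarray(self.counts[:, j].todense()).ravel()
        return col.reshape(self.n_rows, self.n_cols)

    def summed_image(self, genes: Sequence[str]) -> np.ndarray:
        """Dense image of counts summed over a gene list (empty list → zeros)."""
        if not genes:
            return np.zeros((self.n_rows, self.n_cols))
        idx = self.gene_index(genes)
        total = np.asarray(self.counts[:, idx].sum(axis=1)).ravel()
        return total.reshape(self.n_rows, self.n_cols)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_sibling(directory: Path, stems: Sequence[str]) -> Path | None:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / f"{stem}{suffix}"
            if cand.exists():
                return cand
    return None


def _read_index_file(path: Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # 10x-style features files carry (id, name, type); prefer the name column
    if all(len(r) >= 2 for r in rows):
        return [r[1] for r in rows]
    return [r[0] for r in rows]


def _load_matrix(matrix_source: Path) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Return (cells x genes counts, cell ids, gene names) from MTX or dense table."""
    matrix_source = Path(matrix_source)
    if matrix_source.is_dir():
        mtx = _find_sibling(matrix_source, ["matrix.mtx"])
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx under {matrix_source}")
        matrix_source = mtx
    name = matrix_source.name
    if ".mtx" in name:
        directory = matrix_source.parent
        genes_path = _find_sibling(directory, ["features.tsv", "genes.tsv"])
        cells_path = _find_sibling(directory, ["barcodes.tsv", "cells.tsv"])
        if genes_path is None or cells_path is None:
            raise FileNotFoundError(
                f"MTX matrix {matrix_source} needs features/genes and barcodes index files"
            )
        with _open_maybe_gzip(matrix_source, "rb") as fh:
            mat = sp.csr_matrix(scipy.io.mmread(fh))
        genes = _read_index_file(genes_path)
        cells = _read_index_file(cells_path)
        # MatrixMarket matrices are written genes x cells (10x convention)
        if mat.shape == (len(genes), len(cells)):
            mat = mat.T.tocsr()
        elif mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither (genes, cells)="
                f"({len(genes)}, {len(cells)}) nor its transpose"
            )
        return mat, cells, genes
    # delimited dense counts: first column = cell id, remaining columns = genes
    sep = "\t" if name.replace(".gz", "").endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(matrix_source, sep=sep, index_col=0)
    return (
        sp.csr_matrix(frame.to_numpy()),
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
    )


def load_cells(
    matrix_source: str | Path,
    coords_source: str | Path,
    max_missing_fraction: float = 0.2,
) -> CellTable:
    """Join a count matrix with a cell-coordinate table into a :class:`CellTable`.

    Cells present in the matrix but absent from the coordinate file (or vice
    versa) are dropped with a logged count; if the dropped fraction of matrix
    cells exceeds ``max_missing_fraction`` the identifiers are considered
    mismatched and a ``ValueError`` is raised.
    """
    counts, cell_ids, gene_names = _load_matrix(Path(matrix_source))
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("count matrix contains negative entries")

    coords = pd.read_csv(coords_source)
    required = {"cell_id", "x_centroid", "y_centroid"}
    if not required.issubset(coords.columns):
        raise ValueError(f"coordinate table must have columns {sorted(required)}")
    coords = coords.drop_duplicates("cell_id").set_index(
        coords["cell_id"].astype(str)
    )

    ids = pd.Index([str(c) for c in cell_ids])
    keep = ids.isin(coords.index)
    n_dropped_matrix = int((~keep).sum())
    n_dropped_coords = int((~coords.index.isin(ids)).sum())
    if n_dropped_matrix:
        logger.info("dropped %d matrix cells lacking coordinates", n_dropped_matrix)
    if n_dropped_coords:
        logger.info("dropped %d coordinate rows absent from the matrix", n_dropped_coords)
    if len(ids) == 0 or n_dropped_matrix / max(len(ids), 1) > max_missing_fraction:
        raise ValueError(
            f"{n_dropped_matrix}/{len(ids)} matrix cells have no coordinates; "
            "identifier sets look mismatched"
        )

    kept_ids = ids[keep]
    sub = coords.loc[kept_ids]
    return CellTable(
        cell_ids=kept_ids.to_numpy(dtype=object),
        x=sub["x_centroid"].to_numpy(dtype=float),
        y=sub["y_centroid"].to_numpy(dtype=float),
        counts=counts[np.flatnonzero(keep)],
        gene_names=gene_names,
    )


def build_grid(cells: CellTable, pitch: float = 10.0) -> ExpressionGrid:
    """Bin cell counts onto a fixed-pitch lattice.

    Each cell contributes all its counts to the grid square containing its
    centroid under the half-open convention ``[k*pitch, (k+1)*pitch)``.  The
    lattice origin is the minimum coordinate rounded down to a pitch multiple,
    and the lattice spans the data bounding box.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if cells.n_cells == 0:
        raise ValueError("cannot grid an empty cell table")
    ox = np.floor(cells.x.min() / pitch) * pitch
    oy = np.floor(cells.y.min() / pitch) * pitch
    col = np.floor((cells.x - ox) / pitch).astype(int)
    row = np.floor((cells.y - oy) / pitch).astype(int)
    n_cols = int(col.max()) + 1
    n_rows = int(row.max()) + 1
    flat = row * n_cols + col
    # accumulate cell rows into grid rows via a sparse indicator product
    indicator = sp.csr_matrix(
        (np.ones(cells.n_cells), (flat, np.arange(cells.n_cells))),
        shape=(n_rows * n_cols, cells.n_cells),
    )
    grid_counts = (indicator @ cells.counts).tocsr()
    return ExpressionGrid(
        pitch=float(pitch),
        n_cols=n_cols,
        n_rows=n_rows,
        origin=(float(ox), float(oy)),
        counts=grid_counts,
        gene_names=list(cells.gene_names),
    )


def write_cells(cells: CellTable, outdir: str | Path) -> dict[str, Path]:
    """Write a cell table in the MTX + cells.csv dialect :func:`load_cells` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx_path = outdir / "matrix.mtx"
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cells.counts.T))  # genes x cells
    features = outdir / "features.tsv"
    features.write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in cells.gene_names)
    )
    barcodes = outdir / "barcodes.tsv"
    barcodes.write_text("".join(f"{c}\n" for c in cells.cell_ids))
    coords = outdir / "cells.csv"
    pd.DataFrame(
        {"cell_id": cells.cell_ids, "x_centroid": cells.x, "y_centroid": cells.y}
    ).to_csv(coords, index=False)
    return {"matrix": mtx_path, "features": features, "barcodes": barcodes, "cells": coords}


def write_grid(grid: ExpressionGrid, path: str | Path) -> Path:
    """Write a grid as a long table (col,row,gene,count) plus a JSON sidecar."""
    path = Path(path)
    coo = grid.counts.tocoo()
    rows, cols = np.divmod(coo.row, grid.n_cols)
    pd.DataFrame(
        {
            "col": cols,
            "row": rows,
            "gene": [grid.gene_names[j] for j in coo.col],
            "count": coo.data,
        }
    ).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pitch": grid.pitch,
                "origin": list(grid.origin),
                "n_cols": grid.n_cols,
                "n_rows": grid.n_rows,
                "gene_names": grid.gene_names,
            }
        )
    )
    return path


def read_grid(path: str | Path) -> ExpressionGrid:
    """Reload a grid written by :func:`write_grid` bit-exactly."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    table = pd.read_csv(path)
    gene_idx = {g: j for j, g in enumerate(meta["gene_names"])}
    flat = table["row"].to_numpy() * meta["n_cols"] + table["col"].to_numpy()
    cols = np.array([gene_idx[g] for g in table["gene"]], dtype=int)
    counts = sp.csr_matrix(
        (table["count"].to_numpy(), (flat, cols)),
        shape=(meta["n_rows"] * meta["n_cols"], len(meta["gene_names"])),
    )
    return ExpressionGrid(
        pitch=meta["pitch"],
        n_cols=meta["n_cols"],
        n_rows=meta["n_rows"],
        origin=tuple(meta["origin"]),
        counts=counts,
        gene_names=list(meta["gene_names"]),
    )
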