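"""Marker-defined spatial-domain detection on the expression lattice.

A spatial domain here is a connected set of lattice grids whose marker logic
holds: at least one transcript of a positive marker and none of a negative
marker.  The raw mask is denoised once with a 3x3 median (majority) filter,
segmented into individual domains under 8-connectivity and bounded by the
grids that touch background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .grid_io import ExpressionGrid

__all__ = [
    "MarkerSpec",
    "DomainLabeling",
    "detect_pre_domain",
    "median_denoise",
    "extract_boundary",
    "segment_domains",
    "jaccard",
]

# 3x3 structuring element: orthogonal and diagonal neighbours alike
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MarkerSpec:
    """Positive/negative marker gene lists defining a domain identity."""

    positive_genes: tuple[str, ...]
    negative_genes: tuple[str, ...] = ()

    def __init__(self, positive_genes, negative_genes=()):
        object.__setattr__(self, "positive_genes", tuple(positive_genes))
        object.__setattr__(self, "negative_genes", tuple(negative_genes))
        if not self.positive_genes:
            raise ValueError("at least one positive marker gene is required")
        overlap = set(self.positive_genes) & set(self.negative_genes)
        if overlap:
            raise ValueError(f"markers listed as both positive and negative: {sorted(overlap)}")

    def validate(self, grid: ExpressionGrid) -> None:
        known = set(grid.gene_names)
        unknown = [g for g in (*self.positive_genes, *self.negative_genes) if g not in known]
        if unknown:
            raise KeyError(f"marker genes not in the panel: {unknown}")


@dataclass
class DomainLabeling:
    """Connected-component labels (0 = background, 1..n_domains) with stats."""

    labels: np.ndarray
    n_domains: int
    areas: np.ndarray  # grid count per domain, index d-1
    bboxes: np.ndarray  # (n_domains, 4): col_min, row_min, col_max, row_max
    centroids: np.ndarray  # (n_domains, 2): mean (col, row)

    @property
    def domain_ids(self) -> np.ndarray:
        return np.arange(1, self.n_domains + 1)

    def mask_of(self, domain_id: int) -> np.ndarray:
        return self.labels == domain_id


def detect_pre_domain(grid: ExpressionGrid, markers: MarkerSpec) -> np.ndarray:
    """Raw (pre-denoise) domain mask from marker logic.

    A grid belongs to the pre-domain when the summed positive-marker count is
    positive and the summed negative-marker count is zero — the logical
    subtraction of the negative-expressing grid set from the positive one.
    """
    markers.validate(grid)
    pos = grid.summed_image(list(markers.positive_genes))
    mask = pos > 0
    if markers.negative_genes:
        neg = grid.summed_image(list(markers.negative_genes))
        mask &= neg == 0
    return mask


def median_denoise(mask: np.ndarray, kernel: int = 3) -> np.ndarray:
    """One pass of a kernel x kernel median (majority) filter, replicate padding."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be an odd integer >= 3")
    filtered = ndi.median_filter(
        mask.astype(np.uint8), size=kernel, mode="nearest"
    )
    return filtered.astype(bool)


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary grids: domain grids with an 8-neighbour in background.

    The lattice border counts as background, so domains truncated by the
    capture area still close their boundary.  Returned as a boolean lattice;
    every true grid is a domain grid.
    """
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    interior = ndi.binary_erosion(mask, structure=_EIGHT, border_value=0)
    return mask & ~interior


def segment_domains(mask: np.ndarray) -> DomainLabeling:
    """Split a mask into individual domains (8-connected components).

    Labels are assigned 1..D in raster order of each component's first grid,
    which is the deterministic order of the underlying labeller.
    """
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return DomainLabeling(
            labels=labels,
            n_domains=0,
            areas=np.zeros(0, dtype=int),
            bboxes=np.zeros((0, 4), dtype=int),
            centroids=np.zeros((0, 2)),
        )
    ids = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=ids).astype(int)
    slices = ndi.find_objects(labels)
    bboxes = np.array(
        [
            (sl[1].start, sl[0].start, sl[1].stop - 1, sl[0].stop - 1)
            for sl in slices
        ],
        dtype=int,
    )
    cr = ndi.center_of_mass(mask, labels, index=ids)  # (row, col) pairs
    centroids = np.array([(c, r) for r, c in cr])
    return DomainLabeling(labels=labels, n_domains=n, areas=areas, bboxes=bboxes, centroids=centroids)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard agreement |A∩B|/|A∪B| between two masks; 1.0 when both empty."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    union = int(np.count_nonzero(mask_a | mask_b))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(mask_a & mask_b))
    return inter / union
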