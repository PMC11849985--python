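"""Distance-stratified shells and per-domain exclusive microenvironment sections.

The signed distance field is sliced into half-open shells ``(x, x+30]`` µm
(default range (-120, +150]).  Shells inside a domain (upper bound <= 0) are
attributed to the domain whose grids they lie on.  Outer shells are shared
space, so each domain claims only the part of a shell inside its expanded
bounding rectangle, and any grid claimed by two or more rectangles is removed
from every domain's section — ambiguous surroundings belong to no single
domain's microenvironment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DomainLabeling
from .distance import DistanceField
from .grid_io import ExpressionGrid

__all__ = [
    "ShellMap",
    "stratify_shells",
    "exclusive_outer_sections",
    "inner_sections",
    "section_expression",
]

_EPS = 1e-9


@dataclass
class ShellMap:
    """Assignment of grids to half-open distance shells.

    ``index`` maps each grid to the position of its interval in
    ``intervals`` (ascending), or -1 when the grid's distance falls outside
    the stratified range.
    """

    intervals: list[tuple[float, float]]
    index: np.ndarray
    width: float

    def mask(self, interval: tuple[float, float]) -> np.ndarray:
        try:
            k = self.intervals.index(tuple(interval))
        except ValueError:
            raise KeyError(f"no shell {interval}; have {self.intervals}") from None
        return self.index == k

    @property
    def outer_levels(self) -> list[float]:
        """Lower edges x of the outer shells (x, x+width], x >= 0."""
        return [lo for lo, _ in self.intervals if lo >= -_EPS]

    @property
    def inner_intervals(self) -> list[tuple[float, float]]:
        return [iv for iv in self.intervals if iv[1] <= _EPS]


def stratify_shells(
    field: DistanceField,
    width: float = 30.0,
    lower: float = -120.0,
    upper: float = 150.0,
) -> ShellMap:
    """Assign each grid with distance in ``(lower, upper]`` to its shell.

    Membership follows ``x < µ <= x+width``; grids outside the range (or with
    infinite distance) stay unassigned.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if lower >= upper:
        raise ValueError("lower must be below upper")
    n_steps = (upper - lower) / width
    if abs(n_steps - round(n_steps)) > 1e-6:
        raise ValueError("(upper - lower) must be an integer multiple of width")
    n_steps = int(round(n_steps))
    intervals = [(lower + k * width, lower + (k + 1) * width) for k in range(n_steps)]

    mu = field.values
    # ceil((mu - lower)/width) - 1 with a relative epsilon so exact upper
    # bounds land in their own (closed-above) interval
    scaled = (mu - lower) / width
    idx = np.ceil(scaled - _EPS).astype(int) - 1
    assigned = np.isfinite(mu) & (scaled > _EPS) & (idx < n_steps)
    index = np.where(assigned, idx, -1)
    return ShellMap(intervals=intervals, index=index, width=width)


def _expanded_rectangles(
    labeling: DomainLabeling, expand_grids: int, shape: tuple[int, int]
) -> list[tuple[int, int, int, int]]:
    n_rows, n_cols = shape
    rects = []
    for cmin, rmin, cmax, rmax in labeling.bboxes:
        rects.append(
            (
                max(cmin - expand_grids, 0),
                max(rmin - expand_grids, 0),
                min(cmax + expand_grids, n_cols - 1),
                min(rmax + expand_grids, n_rows - 1),
            )
        )
    return rects


def exclusive_outer_sections(
    labeling: DomainLabeling,
    shells: ShellMap,
    level: float,
    pitch: float,
    expand_by_x: bool = False,
) -> dict[int, np.ndarray]:
    """Per-domain exclusive part of the outer shell ``(level, level+width]``.

    Each domain's bounding rectangle is expanded by ``level + width`` µm per
    side (so it geometrically contains the shell; pass ``expand_by_x`` to
    expand by ``level`` µm only) and clipped to the lattice.  A domain's
    section is the shell restricted to its rectangle, minus the union of all
    pairwise rectangle intersections at this level — grids claimed by more
    than one rectangle belong to no domain.
    """
    matches = [lo for lo in shells.outer_levels if abs(lo - level) < 1e-6]
    if not matches:
        raise KeyError(f"no outer shell starts at {level}; have {shells.outer_levels}")
    lo = matches[0]
    shell = shells.mask((lo, lo + shells.width))

    expand_um = level if expand_by_x else level + shells.width
    expand_grids = int(np.ceil(expand_um / pitch - 1e-9))
    rects = _expanded_rectangles(labeling, expand_grids, shell.shape)

    claimed = np.zeros(shell.shape, dtype=np.int32)
    for cmin, rmin, cmax, rmax in rects:
        claimed[rmin : rmax + 1, cmin : cmax + 1] += 1
    contested = claimed >= 2

    sections: dict[int, np.ndarray] = {}
    for d, (cmin, rmin, cmax, rmax) in zip(labeling.domain_ids, rects):
        rect = np.zeros(shell.shape, dtype=bool)
        rect[rmin : rmax + 1, cmin : cmax + 1] = True
        sections[int(d)] = shell & rect & ~contested
    return sections


def inner_sections(
    labeling: DomainLabeling, shells: ShellMap
) -> dict[tuple[int, tuple[float, float]], np.ndarray]:
    """Per-domain inner sections: shells with upper bound <= 0 on own grids.

    Domains are disjoint components, so no rectangle exclusion is needed.
    """
    out: dict[tuple[int, tuple[float, float]], np.ndarray] = {}
    for interval in shells.inner_intervals:
        shell = shells.mask(interval)
        for d in labeling.domain_ids:
            out[(int(d), interval)] = shell & (labeling.labels == d)
    return out


def section_expression(grid: ExpressionGrid, section: np.ndarray) -> pd.Series:
    """Per-gene mean count over a section's grids.

    An empty section has no defined mean: all values are returned missing
    (NaN), never zero.
    """
    if section.shape != grid.shape:
        raise ValueError("section mask must match the grid lattice")
    flat = np.flatnonzero(section.ravel())
    if flat.size == 0:
        return pd.Series(np.nan, index=list(grid.gene_names))
    means = np.asarray(grid.counts[flat].mean(axis=0)).ravel()
    return pd.Series(means, index=list(grid.gene_names))
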