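"""Synthetic in-situ tissue generator with planted spatial structure.

Emulates the data model of a Xenium-style run at desk scale: cells scattered
in a 2-D field by compartment-wise homogeneous Poisson point processes, with
per-gene Poisson transcript counts whose rates depend on the compartment.
Compartments are defined around planted disk-shaped tumor domains:

* ``tumor``  — inside a disk; expresses the positive domain marker (CDH1).
* ``ring``   — a myoepithelial-like annulus of stated width just outside the
  disk edge; expresses the boundary marker (KRT14).
* ``shell``  — stromal cells whose Euclidean distance from the nearest disk
  edge falls in the immune shell interval (default (30, 60] µm); express the
  shell-localised immune marker (CD8A).
* ``stroma`` — everything else outside disks and rings.

Domain phenotypes plant downstream effects: ``infiltrated`` domains express
the endothelial marker (PECAM1) inside the tumor; ``staged`` domains carry a
latent stage s in [0, 1] driving monotone marker gradients (MKI67 up, ACTA2
down).  Ground-truth masks are rasterised with the same binning convention
the gridding stage uses, so detection accuracy can be scored without
off-by-one disputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grid_io import CellTable, ExpressionGrid, build_grid
from .profiles import DomainProfiles

__all__ = [
    "DiskDomain",
    "TissueSpec",
    "GroundTruth",
    "default_gene_rates",
    "breast_like_spec",
    "simulate_tissue",
    "simulate_cohort",
    "simulate_profile_groups",
    "simulate_progression_profiles",
]

MARKERS = {
    "tumor": "CDH1",
    "boundary": "KRT14",
    "shell_immune": "CD8A",
    "endothelial": "PECAM1",
    "stage_up": "MKI67",
    "stage_down": "ACTA2",
    "stroma": "MMP2",
}


@dataclass(frozen=True)
class DiskDomain:
    """A planted disk-shaped spatial domain."""

    center: tuple[float, float]
    radius: float
    phenotype: str = "baseline"  # baseline | infiltrated | staged
    stage: float | None = None  # required for phenotype == "staged"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("domain radius must be positive")
        if self.phenotype not in ("baseline", "infiltrated", "staged"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.phenotype == "staged" and not (
            self.stage is not None and 0.0 <= self.stage <= 1.0
        ):
            raise ValueError("staged domains need stage in [0, 1]")


def default_gene_rates(n_filler: int = 13) -> pd.DataFrame:
    """Per-gene Poisson transcript rates (per cell) by compartment.

    Columns are compartments; the ``tumor_infiltrated`` column applies to
    tumor cells of infiltrated domains.  Filler genes model uninformative
    panel content at a uniform low rate.
    """
    compartments = ["tumor", "tumor_infiltrated", "ring", "shell", "stroma"]
    rows = {
        MARKERS["tumor"]: [20.0, 20.0, 0.05, 0.05, 0.05],
        MARKERS["boundary"]: [0.05, 0.05, 5.0, 0.05, 0.05],
        MARKERS["shell_immune"]: [0.1, 0.1, 0.1, 5.0, 0.1],
        MARKERS["endothelial"]: [0.1, 3.0, 0.2, 0.5, 0.5],
        MARKERS["stage_up"]: [1.0, 1.0, 0.1, 0.1, 0.1],
        MARKERS["stage_down"]: [1.0, 1.0, 2.0, 0.2, 0.2],
        MARKERS["stroma"]: [0.1, 0.1, 0.3, 1.0, 1.0],
    }
    for i in range(n_filler):
        rows[f"FILLER{i + 1:02d}"] = [0.2] * len(compartments)
    return pd.DataFrame(rows, index=compartments).T


@dataclass
class TissueSpec:
    """Study conditions for one synthetic tissue section."""

    field_size: tuple[float, float] = (3800.0, 3250.0)
    domains: list[DiskDomain] = field(default_factory=list)
    densities: dict[str, float] = field(
        default_factory=lambda: {"tumor": 0.02, "ring": 0.015, "stroma": 0.001}
    )
    ring_width: float = 20.0
    immune_shell: tuple[float, float] = (30.0, 60.0)
    gene_rates: pd.DataFrame = field(default_factory=default_gene_rates)
    pitch: float = 10.0
    overdispersion: float | None = None  # NB shape k; None → pure Poisson
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.gene_rates.to_numpy() < 0).any():
            raise ValueError("gene rates must be nonnegative")
        if not self.allow_overlap:
            for i, a in enumerate(self.domains):
                for b in self.domains[i + 1 :]:
                    gap = np.hypot(
                        a.center[0] - b.center[0], a.center[1] - b.center[1]
                    )
                    if gap <= a.radius + b.radius:
                        raise ValueError(
                            f"domains at {a.center} and {b.center} overlap"
                        )

    @property
    def gene_names(self) -> list[str]:
        return list(self.gene_rates.index)


def breast_like_spec(
    n_domains: int = 42,
    radius: float = 150.0,
    infiltrated_fraction: float = 0.5,
    staged: bool = False,
    seed: int = 0,
) -> TissueSpec:
    """Default study conditions: a lattice of jittered carcinoma-like disks.

    Domain radii match DCIS-scale ducts (a few hundred µm across) so that
    the one-grid rim uncertainty of marker-threshold detection stays small
    relative to the domain area.  Domains sit on a jittered rectangular
    lattice with ~550 µm spacing so microenvironment shells rarely contend;
    alternate domains are flagged ``infiltrated`` (or assigned a latent
    stage when ``staged``).
    """
    rng = np.random.default_rng(seed)
    n_x = int(np.ceil(np.sqrt(n_domains * 7 / 6)))
    n_y = int(np.ceil(n_domains / n_x))
    spacing = 550.0
    margin = 250.0
    domains: list[DiskDomain] = []
    k = 0
    for iy in range(n_y):
        for ix in range(n_x):
            if k >= n_domains:
                break
            cx = margin + ix * spacing + rng.uniform(-30, 30)
            cy = margin + iy * spacing + rng.uniform(-30, 30)
            if staged:
                stage = k / max(n_domains - 1, 1)
                domains.append(
                    DiskDomain((cx, cy), radius, phenotype="staged", stage=stage)
                )
            else:
                phen = "infiltrated" if k < round(n_domains * infiltrated_fraction) else "baseline"
                domains.append(DiskDomain((cx, cy), radius, phenotype=phen))
            k += 1
    width = margin * 2 + (n_x - 1) * spacing
    height = margin * 2 + (n_y - 1) * spacing
    return TissueSpec(field_size=(width, height), domains=domains, seed=seed)


@dataclass
class GroundTruth:
    """Planted truth rasterised on the analysis lattice."""

    mask: np.ndarray  # true domain mask (n_rows, n_cols)
    domain_of_grid: np.ndarray  # planted domain index + 1, 0 = background
    origin: tuple[float, float]
    pitch: float
    phenotypes: list[str]
    stages: list[float | None]
    compartment_of_cell: np.ndarray
    domain_of_cell: np.ndarray  # planted domain index + 1, 0 = none


def _signed_edge_distance(
    x: np.ndarray, y: np.ndarray, spec: TissueSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance to the nearest disk edge (negative inside) and disk id."""
    d = np.full(x.shape, np.inf)
    which = np.zeros(x.shape, dtype=int)
    for i, dom in enumerate(spec.domains):
        di = np.hypot(x - dom.center[0], y - dom.center[1]) - dom.radius
        closer = di < d
        d[closer] = di[closer]
        which[closer] = i + 1
    return d, which


def _sample_counts(
    rng: np.random.Generator, rates: np.ndarray, overdispersion: float | None
) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(rates)
    # gamma-poisson mixture with shape k: mean preserved, var = m + m^2/k
    lam = rng.gamma(overdispersion, rates / overdispersion)
    return rng.poisson(lam)


def simulate_tissue(spec: TissueSpec, seed: int | None = None) -> tuple[CellTable, GroundTruth]:
    """Simulate one tissue section and its rasterised ground truth.

    Cells are placed by homogeneous Poisson point processes per compartment
    and transcripts drawn per gene at the compartment's rate.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    w, h = spec.field_size
    xs, ys, compartment, domain_of_cell = [], [], [], []

    for i, dom in enumerate(spec.domains):
        r_out = dom.radius + spec.ring_width
        # tumor disk
        n_t = rng.poisson(spec.densities["tumor"] * np.pi * dom.radius**2)
        rad = dom.radius * np.sqrt(rng.uniform(size=n_t))
        ang = rng.uniform(0, 2 * np.pi, size=n_t)
        xs.append(dom.center[0] + rad * np.cos(ang))
        ys.append(dom.center[1] + rad * np.sin(ang))
        compartment += ["tumor"] * n_t
        domain_of_cell += [i + 1] * n_t
        # boundary ring annulus
        area_ring = np.pi * (r_out**2 - dom.radius**2)
        n_r = rng.poisson(spec.densities["ring"] * area_ring)
        rad = np.sqrt(rng.uniform(dom.radius**2, r_out**2, size=n_r))
        ang = rng.uniform(0, 2 * np.pi, size=n_r)
        xs.append(dom.center[0] + rad * np.cos(ang))
        ys.append(dom.center[1] + rad * np.sin(ang))
        compartment += ["ring"] * n_r
        domain_of_cell += [i + 1] * n_r

    # stroma: uniform over the field, thinned where disks/rings already occupy
    n_s = rng.poisson(spec.densities["stroma"] * w * h)
    sx = rng.uniform(0, w, size=n_s)
    sy = rng.uniform(0, h, size=n_s)
    edge_dist, _ = _signed_edge_distance(sx, sy, spec)
    keep = edge_dist > spec.ring_width
    sx, sy, edge_dist = sx[keep], sy[keep], edge_dist[keep]
    lo, hi = spec.immune_shell
    in_shell = (edge_dist > lo) & (edge_dist <= hi)
    xs.append(sx)
    ys.append(sy)
    compartment += list(np.where(in_shell, "shell", "stroma"))
    domain_of_cell += [0] * sx.size

    x = np.concatenate(xs) if xs else np.zeros(0)
    y = np.concatenate(ys) if ys else np.zeros(0)
    compartment = np.asarray(compartment, dtype=object)
    domain_of_cell = np.asarray(domain_of_cell, dtype=int)
    n_cells = x.size
    if n_cells == 0:
        raise ValueError("simulated tissue produced no cells; raise densities")

    genes = spec.gene_names
    rates = np.zeros((n_cells, len(genes)))
    base = {
        c: spec.gene_rates[c].to_numpy()
        for c in ("tumor", "tumor_infiltrated", "ring", "shell", "stroma")
    }
    for c in ("ring", "shell", "stroma"):
        rates[compartment == c] = base[c]
    up = spec.gene_rates.index.get_loc(MARKERS["stage_up"])
    down = spec.gene_rates.index.get_loc(MARKERS["stage_down"])
    for i, dom in enumerate(spec.domains):
        sel = (compartment == "tumor") & (domain_of_cell == i + 1)
        if dom.phenotype == "infiltrated":
            rates[sel] = base["tumor_infiltrated"]
        else:
            rates[sel] = base["tumor"]
        if dom.phenotype == "staged":
            rates[sel, up] = 1.0 + 9.0 * dom.stage
            rates[sel, down] = 10.0 - 9.0 * dom.stage
    counts = _sample_counts(rng, rates, spec.overdispersion)

    cells = CellTable(
        cell_ids=np.array([f"cell_{i:06d}" for i in range(n_cells)], dtype=object),
        x=x,
        y=y,
        counts=sp.csr_matrix(counts),
        gene_names=genes,
    )

    # rasterise truth with the gridding stage's own binning convention
    grid = build_grid(cells, spec.pitch)
    ox, oy = grid.origin
    cc, rr = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))
    gx = ox + (cc + 0.5) * spec.pitch
    gy = oy + (rr + 0.5) * spec.pitch
    edge, which = _signed_edge_distance(gx.ravel(), gy.ravel(), spec)
    inside = edge <= 0
    mask = inside.reshape(grid.n_rows, grid.n_cols)
    domain_of_grid = np.where(inside, which, 0).reshape(grid.n_rows, grid.n_cols)

    truth = GroundTruth(
        mask=mask,
        domain_of_grid=domain_of_grid,
        origin=grid.origin,
        pitch=spec.pitch,
        phenotypes=[d.phenotype for d in spec.domains],
        stages=[d.stage for d in spec.domains],
        compartment_of_cell=compartment,
        domain_of_cell=domain_of_cell,
    )
    return cells, truth


def simulate_cohort(
    base_spec: TissueSpec,
    n_samples: int,
    seed: int = 0,
    nuisance_sigma: float = 0.0,
    samples_per_patient: int = 1,
) -> list[dict]:
    """Simulate a multi-sample cohort sharing one gene panel.

    Phenotype effects are shared across samples; an optional lognormal
    sample-level rate multiplier (``nuisance_sigma``) models section-to-
    section technical shifts.  Returns one record per sample with keys
    ``cells``, ``truth``, ``sample_id``, ``patient_id``.
    """
    if n_samples < 2:
        raise ValueError("a cohort needs at least two samples")
    rng = np.random.default_rng(seed)
    records = []
    for s in range(n_samples):
        spec_s = replace(base_spec)
        if nuisance_sigma > 0:
            factor = float(rng.lognormal(0.0, nuisance_sigma))
            spec_s = replace(base_spec, gene_rates=base_spec.gene_rates * factor)
        cells, truth = simulate_tissue(spec_s, seed=int(rng.integers(0, 2**31 - 1)))
        records.append(
            {
                "cells": cells,
                "truth": truth,
                "sample_id": f"sample_{s:02d}",
                "patient_id": f"patient_{s // samples_per_patient:02d}",
            }
        )
    return records


def simulate_profile_groups(
    n_per_group: int = 30,
    n_genes: int = 20,
    separation: float = 8.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> DomainProfiles:
    """Two well-separated planted populations of domain profiles.

    Group A expresses the first half of the panel at ``separation``-fold the
    baseline, group B the second half; multiplicative lognormal noise.  The
    planted label is stored in ``meta['planted_group']``.
    """
    rng = np.random.default_rng(seed)
    half = n_genes // 2
    means = np.full((2, n_genes), 1.0)
    means[0, :half] *= separation
    means[1, half:] *= separation
    labels = np.repeat([0, 1], n_per_group)
    noise = rng.lognormal(0.0, noise_sigma, size=(2 * n_per_group, n_genes))
    values = means[labels] * noise
    idx = pd.Index(np.arange(1, 2 * n_per_group + 1), name="domain_id")
    expression = pd.DataFrame(
        values, index=idx, columns=[f"G{j + 1:02d}" for j in range(n_genes)]
    )
    meta = pd.DataFrame({"planted_group": labels, "area": 100}, index=idx)
    return DomainProfiles(expression=expression, meta=meta)


def simulate_progression_profiles(
    n: int = 60,
    n_genes: int = 20,
    n_gradient: int = 6,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> DomainProfiles:
    """Profiles ordered by a latent stage s with monotone marker gradients.

    Half the gradient genes rise linearly with s (1 → 10), half fall; the
    remaining genes are flat baseline.  The stage is stored in
    ``meta['planted_stage']``.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n)
    means = np.full((n, n_genes), 1.0)
    for j in range(n_gradient):
        if j % 2 == 0:
            means[:, j] = 1.0 + 9.0 * s
        else:
            means[:, j] = 10.0 - 9.0 * s
    values = means * rng.lognormal(0.0, noise_sigma, size=(n, n_genes))
    idx = pd.Index(np.arange(1, n + 1), name="domain_id")
    expression = pd.DataFrame(
        values, index=idx, columns=[f"G{j + 1:02d}" for j in range(n_genes)]
    )
    meta = pd.DataFrame({"planted_stage": s, "area": 100}, index=idx)
    return DomainProfiles(expression=expression, meta=meta)
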