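"""Microenvironment expression statistics by stratified section.

Expression per section is summarised as a density (total counts divided by
the section's grid count) and compared between groups with a generalised
linear model whose terms are section, group and their interaction.  A
correlation screen ranks genes by the Pearson similarity of their section-
density profile to a reference gene (threshold 0.75 by default), and an
omnibus Kruskal-Wallis test compares clusters within a section.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .grid_io import ExpressionGrid

__all__ = [
    "expression_density",
    "GLMResult",
    "fit_section_glm",
    "correlate_with_reference",
    "KruskalResult",
    "compare_sections",
]


def expression_density(
    grid: ExpressionGrid,
    sections: Mapping[object, Mapping[tuple[float, float], np.ndarray]],
    genes: Sequence[str] | None = None,
    groups: Mapping[object, object] | None = None,
) -> pd.DataFrame:
    """Long table of expression density per (unit, section, gene).

    ``sections`` maps an analysis unit (ROI or domain id) to its section
    masks keyed by interval.  Density is total counts in the section divided
    by its grid count; empty sections yield missing values which downstream
    models exclude.
    """
    genes = list(genes) if genes is not None else list(grid.gene_names)
    gidx = grid.gene_index(genes)
    records = []
    for unit, interval_masks in sections.items():
        group = groups.get(unit) if groups is not None else None
        for interval, mask in interval_masks.items():
            flat = np.flatnonzero(np.asarray(mask).ravel())
            if flat.size:
                totals = np.asarray(grid.counts[flat][:, gidx].sum(axis=0)).ravel()
                dens = totals / flat.size
            else:
                dens = np.full(len(genes), np.nan)
            mid = 0.5 * (interval[0] + interval[1])
            for g, v in zip(genes, dens):
                records.append(
                    {
                        "unit": unit,
                        "section_low": interval[0],
                        "section_high": interval[1],
                        "section_mid": mid,
                        "group": group,
                        "gene": g,
                        "n_grids": int(flat.size),
                        "density": v,
                    }
                )
    return pd.DataFrame.from_records(records)


@dataclass
class GLMResult:
    """Coefficients, 95% CIs and p-values for section, group and interaction."""

    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    family: str
    coding: str
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "ci_low": self.conf_int[0],
                "ci_high": self.conf_int[1],
                "p": self.pvalues,
            }
        )
        return out


def _design_matrix(sub: pd.DataFrame, coding: str) -> pd.DataFrame:
    group_codes = pd.Categorical(sub["group"]).codes.astype(float)
    if coding == "ordinal":
        section = sub["section_mid"].astype(float)
        design = pd.DataFrame(
            {
                "const": 1.0,
                "section": section,
                "group": group_codes,
                "section:group": section * group_codes,
            },
            index=sub.index,
        )
    elif coding == "categorical":
        dummies = pd.get_dummies(
            sub["section_mid"].astype(float), prefix="section", drop_first=True
        ).astype(float)
        design = pd.concat(
            [
                pd.Series(1.0, index=sub.index, name="const"),
                dummies,
                pd.Series(group_codes, index=sub.index, name="group"),
                dummies.mul(group_codes, axis=0).add_suffix(":group"),
            ],
            axis=1,
        )
    else:
        raise ValueError("coding must be 'ordinal' or 'categorical'")
    return design


def fit_section_glm(
    table: pd.DataFrame,
    gene: str,
    coding: str = "ordinal",
    family: sm.families.Family | None = None,
) -> GLMResult:
    """GLM of expression density on section, group and their interaction.

    Default family is Gaussian with identity link (a Poisson/log family can
    be passed for count-like densities).  Sections are coded by their µm
    interval midpoint by default; ``coding='categorical'`` uses dummies.
    Missing densities (empty sections) are excluded.
    """
    sub = table[(table["gene"] == gene) & table["density"].notna()]
    if sub.empty:
        raise ValueError(f"no density rows for gene {gene!r}")
    if sub["section_mid"].nunique() < 2:
        raise ValueError("design is rank deficient: need at least two sections")
    if sub["group"].nunique() != 2:
        raise ValueError("exactly two groups are required")
    design = _design_matrix(sub, coding)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify the first column whose removal restores full rank
        for col in design.columns[1:]:
            reduced = design.drop(columns=col)
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"design is rank deficient: term {col!r} is collinear")
        raise ValueError("design is rank deficient")
    fam = family if family is not None else sm.families.Gaussian()
    model = sm.GLM(sub["density"].to_numpy(dtype=float), design, family=fam)
    fit = model.fit()
    return GLMResult(
        params=fit.params,
        conf_int=fit.conf_int(),
        pvalues=fit.pvalues,
        family=type(fam).__name__,
        coding=coding,
        n_obs=int(fit.nobs),
    )


def correlate_with_reference(
    profiles: pd.DataFrame,
    reference: str,
    threshold: float = 0.75,
    include_reference: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each gene's section-density profile with a reference.

    ``profiles`` has one row per gene and one column per section (a shared
    section grid).  Zero-variance genes get a missing correlation and never
    pass.  Returns a frame sorted by descending r with a ``passes`` column
    (``r >= threshold``).
    """
    if reference not in profiles.index:
        raise KeyError(f"reference gene {reference!r} not in profiles")
    ref = profiles.loc[reference].to_numpy(dtype=float)
    if np.std(ref) == 0:
        raise ValueError("reference profile has zero variance")
    rows = []
    for gene, prof in profiles.iterrows():
        if gene == reference and not include_reference:
            continue
        v = prof.to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(ref)
        if ok.sum() < 2 or np.std(v[ok]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(v[ok], ref[ok])[0, 1])
        rows.append({"gene": gene, "r": r, "passes": bool(r >= threshold) if np.isfinite(r) else False})
    out = pd.DataFrame(rows).set_index("gene")
    return out.sort_values("r", ascending=False, na_position="last")


@dataclass
class KruskalResult:
    statistic: float
    pvalue: float
    pvalue_adjusted: float
    n_groups: int


def compare_sections(
    groups: Mapping[object, Sequence[float]] | Sequence[Sequence[float]],
    bonferroni_m: int = 1,
) -> KruskalResult:
    """Kruskal-Wallis omnibus comparison of a gene's section values by cluster.

    ``bonferroni_m`` multiplies the p-value for a correction across the
    genes/sections of a screening family (capped at 1).
    """
    if isinstance(groups, Mapping):
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
    samples = [s[np.isfinite(s)] for s in samples]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least two clusters")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every cluster needs at least two units")
    stat, p = scipy.stats.kruskal(*samples)
    return KruskalResult(
        statistic=float(stat),
        pvalue=float(p),
        pvalue_adjusted=float(min(1.0, p * bonferroni_m)),
        n_groups=len(samples),
    )
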