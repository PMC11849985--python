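"""Clustering, embedding, abstract-graph trajectory and pseudotime of domains.

Domain pseudobulk profiles are treated like a small single-cell experiment:
log1p → PCA (50 components by default) → k-nearest-neighbour graph → Leiden
communities → 2-D embedding (UMAP or t-SNE), then partition-based graph
abstraction over the clusters and diffusion pseudotime anchored at a chosen
root cluster.  All numerics delegate to scanpy/anndata under fixed-seed
contracts; this module owns the orchestration, the deterministic root rule
and the provenance bookkeeping for multi-sample integration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

from .profiles import DomainProfiles

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "TrajectoryResult",
    "cluster_domains",
    "trajectory",
    "path_heatmap",
    "integrate_samples",
]


@dataclass
class ClusteringResult:
    labels: pd.Series  # per-domain cluster label (int), index = domain index
    embedding: pd.DataFrame  # 2-D coordinates
    pcs: pd.DataFrame  # principal-component scores
    seed: int
    params: dict
    adata: ad.AnnData  # processed object reused by the trajectory stage


@dataclass
class TrajectoryResult:
    pseudotime: pd.Series  # per-domain, root unit at 0
    root_cluster: int
    root_domain: object  # index label of the anchoring unit
    connectivities: pd.DataFrame  # cluster-level abstract graph edge confidences


def _profiles_to_adata(profiles: DomainProfiles) -> ad.AnnData:
    obs = profiles.meta.copy()
    obs.index = obs.index.astype(str)
    return ad.AnnData(
        X=profiles.expression.to_numpy(dtype=np.float32),
        obs=obs,
        var=pd.DataFrame(index=profiles.expression.columns),
    )


def cluster_domains(
    profiles: DomainProfiles,
    n_pcs: int = 50,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    embedding: str = "umap",
) -> ClusteringResult:
    """log1p → PCA → kNN graph → Leiden → 2-D embedding, all seeded.

    ``n_pcs`` and ``k_neighbors`` are clipped (with a warning) when the
    profile matrix is too small for them; the embedding backend (``umap`` or
    ``tsne``) never affects the labels.
    """
    if profiles.n_domains < 2:
        raise ValueError("clustering needs at least two domains")
    adata = _profiles_to_adata(profiles)
    sc.pp.log1p(adata)

    max_pcs = min(adata.n_obs - 1, adata.n_vars - 1)
    if n_pcs > max_pcs:
        logger.warning("n_pcs=%d clipped to %d for %d domains x %d genes",
                       n_pcs, max_pcs, adata.n_obs, adata.n_vars)
        n_pcs = max_pcs
    if k_neighbors >= adata.n_obs:
        logger.warning("k_neighbors=%d clipped to %d", k_neighbors, adata.n_obs - 1)
        k_neighbors = adata.n_obs - 1

    with warnings.catch_warnings():
        # zero-variance input makes the explained-variance ratio 0/0; the
        # scores themselves are well-defined (all zero)
        warnings.simplefilter("ignore", RuntimeWarning)
        sc.pp.pca(adata, n_comps=n_pcs, svd_solver="full", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=k_neighbors, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg", key_added="cluster")
    if embedding == "umap":
        sc.tl.umap(adata, random_state=seed)
        coords = adata.obsm["X_umap"]
    elif embedding == "tsne":
        perplexity = min(30.0, max(2.0, (adata.n_obs - 1) / 3.0))
        sc.tl.tsne(adata, random_state=seed, perplexity=perplexity)
        coords = adata.obsm["X_tsne"]
    else:
        raise ValueError("embedding must be 'umap' or 'tsne'")

    index = profiles.expression.index
    labels = pd.Series(
        adata.obs["cluster"].astype(int).to_numpy(), index=index, name="cluster"
    )
    result = ClusteringResult(
        labels=labels,
        embedding=pd.DataFrame(coords, index=index, columns=["dim1", "dim2"]),
        pcs=pd.DataFrame(
            adata.obsm["X_pca"], index=index,
            columns=[f"PC{i + 1}" for i in range(adata.obsm["X_pca"].shape[1])],
        ),
        seed=seed,
        params={"n_pcs": n_pcs, "k_neighbors": k_neighbors,
                "resolution": resolution, "embedding": embedding},
        adata=adata,
    )
    profiles.meta["cluster"] = labels
    return result


def _root_unit(clustering: ClusteringResult, root_cluster: int):
    """Deterministic root: the domain nearest its cluster centroid in PC space."""
    members = clustering.labels.index[clustering.labels == root_cluster]
    if len(members) == 0:
        raise ValueError(f"root cluster {root_cluster} has no members")
    pcs = clustering.pcs.loc[members]
    centroid = pcs.mean(axis=0)
    return ((pcs - centroid) ** 2).sum(axis=1).idxmin()


def trajectory(
    profiles: DomainProfiles,
    clustering: ClusteringResult,
    root_cluster: int,
) -> TrajectoryResult:
    """Cluster-level abstract graph plus diffusion pseudotime from a root.

    The root unit is the domain nearest the root cluster's centroid in PC
    space; its pseudotime is 0 and the minimum over all domains.
    """
    n_clusters = clustering.labels.nunique()
    if n_clusters < 2:
        raise ValueError("trajectory needs at least two clusters")
    if root_cluster not in set(clustering.labels):
        raise ValueError(f"root cluster {root_cluster} not among labels")

    adata = clustering.adata
    adata.obs["cluster"] = adata.obs["cluster"].astype("category")
    sc.tl.paga(adata, groups="cluster")
    root = _root_unit(clustering, root_cluster)
    adata.uns["iroot"] = int(np.flatnonzero(adata.obs_names == str(root))[0])
    sc.tl.diffmap(adata, random_state=clustering.seed)
    sc.tl.dpt(adata)

    index = profiles.expression.index
    pseudotime = pd.Series(
        adata.obs["dpt_pseudotime"].to_numpy(), index=index, name="pseudotime"
    )
    if not np.isfinite(pseudotime.to_numpy()).all():
        raise RuntimeError("non-finite pseudotime; neighbour graph may be disconnected")
    cats = [int(c) for c in adata.obs["cluster"].cat.categories]
    conn = pd.DataFrame(
        np.asarray(adata.uns["paga"]["connectivities"].todense()),
        index=cats, columns=cats,
    )
    profiles.meta["pseudotime"] = pseudotime
    return TrajectoryResult(
        pseudotime=pseudotime,
        root_cluster=root_cluster,
        root_domain=root,
        connectivities=conn,
    )


@dataclass
class PathHeatmap:
    matrix: pd.DataFrame  # genes x domains, per-gene scaled to [0, 1]
    order: pd.Index  # domains along the path, ascending pseudotime
    flat_genes: list[str]  # constant along the path; rows forced to zero


def path_heatmap(
    profiles: DomainProfiles,
    pseudotime: pd.Series,
    path_clusters: list[int],
    genes: list[str],
) -> PathHeatmap:
    """Gene x domain matrix along a progression path, ordered by pseudotime.

    Values are min-max scaled per gene; genes constant along the path are
    returned as all-zero rows and flagged.
    """
    if "cluster" not in profiles.meta:
        raise ValueError("profiles carry no cluster labels; run clustering first")
    on_path = profiles.meta.index[profiles.meta["cluster"].isin(path_clusters)]
    if len(on_path) == 0:
        raise ValueError(f"no domains in path clusters {path_clusters}")
    missing = [g for g in genes if g not in profiles.expression.columns]
    if missing:
        raise KeyError(f"genes not in panel: {missing}")
    order = pseudotime.loc[on_path].sort_values(kind="stable").index
    block = profiles.expression.loc[order, genes].T
    lo = block.min(axis=1)
    span = block.max(axis=1) - lo
    flat = span == 0
    span = span.mask(flat, 1.0)
    scaled = block.sub(lo, axis=0).div(span, axis=0)
    scaled.loc[flat] = 0.0
    return PathHeatmap(matrix=scaled, order=order, flat_genes=list(block.index[flat]))


def integrate_samples(per_sample: list[DomainProfiles]) -> DomainProfiles:
    """Concatenate domain profiles from several samples on the shared panel.

    Columns are the intersection of the gene panels (dropped genes logged);
    rows get a ``sample::domain`` index so downstream clustering is unchanged.
    Every input must carry ``sample_id`` in its metadata.
    """
    if not per_sample:
        raise ValueError("no profile matrices supplied")
    panels = [set(p.expression.columns) for p in per_sample]
    shared = set.intersection(*panels)
    if not shared:
        raise ValueError("gene panels share no genes; cannot integrate")
    dropped = sorted(set.union(*panels) - shared)
    if dropped:
        logger.info("integration drops %d genes outside the shared panel: %s",
                    len(dropped), dropped[:10])
    genes = [g for g in per_sample[0].expression.columns if g in shared]

    expr_parts, meta_parts = [], []
    for p in per_sample:
        if "sample_id" not in p.meta.columns:
            raise ValueError("each profile matrix needs a sample_id metadata column")
        sid = str(p.meta["sample_id"].iloc[0])
        idx = pd.Index([f"{sid}::{d}" for d in p.expression.index], name="domain_id")
        expr_parts.append(p.expression[genes].set_axis(idx))
        meta_parts.append(p.meta.set_axis(idx))
    return DomainProfiles(
        expression=pd.concat(expr_parts), meta=pd.concat(meta_parts)
    )
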