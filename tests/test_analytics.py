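"""Clustering/trajectory orchestration: planted recovery and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from spatialshell import (
    cluster_domains,
    integrate_samples,
    path_heatmap,
    simulate_profile_groups,
    simulate_progression_profiles,
    trajectory,
)
from spatialshell.profiles import DomainProfiles


@pytest.fixture(scope="module")
def planted_groups():
    return simulate_profile_groups(n_per_group=30, seed=3)


@pytest.fixture(scope="module")
def planted_clustering(planted_groups):
    return cluster_domains(planted_groups, seed=0)


def test_planted_partition_recovered_exactly(planted_groups, planted_clustering):
    ari = adjusted_rand_score(
        planted_groups.meta["planted_group"], planted_clustering.labels
    )
    assert ari == pytest.approx(1.0)


def test_clustering_deterministic_under_seed(planted_groups, planted_clustering):
    again = cluster_domains(simulate_profile_groups(n_per_group=30, seed=3), seed=0)
    assert (again.labels.to_numpy() == planted_clustering.labels.to_numpy()).all()
    np.testing.assert_array_equal(
        again.embedding.to_numpy(), planted_clustering.embedding.to_numpy()
    )


def test_identical_profiles_form_single_cluster():
    row = np.array([3.0, 1.0, 0.5, 2.0, 0.0, 4.0])
    expr = pd.DataFrame(
        np.tile(row, (12, 1)),
        index=pd.Index(range(1, 13), name="domain_id"),
        columns=[f"G{i}" for i in range(6)],
    )
    prof = DomainProfiles(expression=expr, meta=pd.DataFrame(index=expr.index))
    res = cluster_domains(prof, n_pcs=3, k_neighbors=5, seed=0)
    assert res.labels.nunique() == 1


def test_labels_independent_of_embedding_backend(planted_groups):
    umap_run = cluster_domains(simulate_profile_groups(seed=3), seed=0, embedding="umap")
    tsne_run = cluster_domains(simulate_profile_groups(seed=3), seed=0, embedding="tsne")
    assert (umap_run.labels.to_numpy() == tsne_run.labels.to_numpy()).all()


def test_cluster_count_nondecreasing_in_resolution(planted_groups):
    counts = []
    for res in (0.25, 1.0, 4.0):
        run = cluster_domains(simulate_profile_groups(seed=3), resolution=res, seed=0)
        counts.append(run.labels.nunique())
    assert counts == sorted(counts)


def test_too_few_domains_rejected():
    expr = pd.DataFrame([[1.0, 2.0]], index=pd.Index([1]), columns=["A", "B"])
    prof = DomainProfiles(expression=expr, meta=pd.DataFrame(index=expr.index))
    with pytest.raises(ValueError):
        cluster_domains(prof)


# ---------------------------------------------------------------- trajectory
@pytest.fixture(scope="module")
def progression():
    prof = simulate_progression_profiles(n=60, seed=5)
    clustering = cluster_domains(prof, seed=0)
    # root = the cluster holding the earliest planted stage
    root = int(clustering.labels.loc[prof.meta["planted_stage"].idxmin()])
    traj = trajectory(prof, clustering, root)
    return prof, clustering, root, traj


def test_pseudotime_root_anchoring(progression):
    prof, clustering, root, traj = progression
    assert traj.pseudotime.min() == pytest.approx(0.0)
    assert clustering.labels[traj.pseudotime.idxmin()] == root
    assert traj.pseudotime.loc[traj.root_domain] == pytest.approx(0.0)


def test_pseudotime_tracks_planted_stage(progression):
    prof, _, _, traj = progression
    rho = spearmanr(traj.pseudotime, prof.meta["planted_stage"]).statistic
    assert rho >= 0.9


def test_pseudotime_invariant_to_row_and_column_order(progression):
    prof, _, root, traj = progression
    rng = np.random.default_rng(0)
    shuffled = DomainProfiles(
        expression=prof.expression.sample(frac=1, random_state=1)[
            rng.permutation(prof.expression.columns)
        ],
        meta=prof.meta.sample(frac=1, random_state=1),
    )
    clustering2 = cluster_domains(shuffled, seed=0)
    root2 = int(clustering2.labels.loc[shuffled.meta["planted_stage"].idxmin()])
    traj2 = trajectory(shuffled, clustering2, root2)
    aligned = traj2.pseudotime.reindex(traj.pseudotime.index)
    assert np.allclose(aligned.to_numpy(), traj.pseudotime.to_numpy(), atol=1e-5)


def test_trajectory_requires_multiple_clusters():
    row = np.array([1.0, 2.0, 3.0])
    expr = pd.DataFrame(
        np.tile(row, (8, 1)), index=pd.Index(range(1, 9)), columns=list("ABC")
    )
    prof = DomainProfiles(expression=expr, meta=pd.DataFrame(index=expr.index))
    clustering = cluster_domains(prof, n_pcs=2, k_neighbors=4, seed=0)
    assert clustering.labels.nunique() == 1  # identical profiles: one community
    with pytest.raises(ValueError):
        trajectory(prof, clustering, 0)


def test_paga_graph_covers_all_clusters(progression):
    _, clustering, _, traj = progression
    assert set(traj.connectivities.index) == set(clustering.labels.unique())
    np.testing.assert_allclose(
        traj.connectivities.to_numpy(), traj.connectivities.to_numpy().T
    )


# --------------------------------------------------------------- path heatmap
def test_path_heatmap_orders_and_scales(progression):
    prof, clustering, root, traj = progression
    clusters = list(clustering.labels.unique())
    genes = ["G01", "G02", "G07"]
    hm = path_heatmap(prof, traj.pseudotime, clusters, genes)
    assert list(hm.matrix.index) == genes
    pt = traj.pseudotime.loc[hm.order].to_numpy()
    assert (np.diff(pt) >= 0).all()
    assert hm.matrix.to_numpy().min() >= 0 and hm.matrix.to_numpy().max() <= 1


def test_path_heatmap_monotone_gene_tracks_position(progression):
    prof, clustering, root, traj = progression
    hm = path_heatmap(
        prof, traj.pseudotime, list(clustering.labels.unique()), ["G01"]
    )
    rho = spearmanr(hm.matrix.loc["G01"], np.arange(hm.matrix.shape[1])).statistic
    assert abs(rho) >= 0.8


def test_path_heatmap_flat_gene_flagged(progression):
    prof, clustering, root, traj = progression
    flat_prof = DomainProfiles(
        expression=prof.expression.assign(FLAT=2.5), meta=prof.meta
    )
    hm = path_heatmap(flat_prof, traj.pseudotime, list(clustering.labels.unique()), ["FLAT"])
    assert hm.flat_genes == ["FLAT"]
    assert (hm.matrix.loc["FLAT"] == 0).all()


def test_path_heatmap_empty_path_errors(progression):
    prof, clustering, root, traj = progression
    with pytest.raises(ValueError):
        path_heatmap(prof, traj.pseudotime, [999], ["G01"])


# ---------------------------------------------------------------- integration
def _with_sample(prof: DomainProfiles, sid: str) -> DomainProfiles:
    meta = prof.meta.copy()
    meta["sample_id"] = sid
    return DomainProfiles(expression=prof.expression, meta=meta)


def test_integration_concatenates_and_intersects():
    a = _with_sample(simulate_profile_groups(n_per_group=5, seed=1), "s1")
    b = _with_sample(simulate_profile_groups(n_per_group=7, seed=2), "s2")
    merged = integrate_samples([a, b])
    assert merged.n_domains == a.n_domains + b.n_domains
    assert merged.gene_names == a.gene_names

    b_small = DomainProfiles(
        expression=b.expression.iloc[:, :10], meta=b.meta
    )
    merged2 = integrate_samples([a, b_small])
    assert merged2.gene_names == a.gene_names[:10]


def test_integration_empty_intersection_errors():
    a = _with_sample(simulate_profile_groups(n_per_group=3, seed=1), "s1")
    renamed = DomainProfiles(
        expression=a.expression.rename(columns=lambda g: g + "_x"), meta=a.meta
    )
    with pytest.raises(ValueError):
        integrate_samples([a, renamed])


def test_cohort_clusters_by_phenotype_not_sample():
    samples = [
        _with_sample(simulate_profile_groups(n_per_group=15, seed=s), f"s{s}")
        for s in (1, 2, 3)
    ]
    merged = integrate_samples(samples)
    res = cluster_domains(merged, seed=0)
    ari_phen = adjusted_rand_score(merged.meta["planted_group"], res.labels)
    ari_sample = adjusted_rand_score(
        merged.meta["sample_id"].astype("category").cat.codes, res.labels
    )
    assert ari_phen >= 0.8
    assert ari_sample < 0.2
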