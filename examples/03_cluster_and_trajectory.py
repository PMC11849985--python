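"""Cluster domain pseudobulk profiles and order them along a trajectory.

Uses planted profile fixtures: (a) two well-separated domain populations,
recovered exactly by the log1p → PCA → kNN → Leiden pipeline; (b) a planted
1-D progression with monotone marker gradients, recovered by PAGA +
diffusion pseudotime anchored at the earliest cluster.
"""

from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

import spatialshell as ss

groups = ss.simulate_profile_groups(n_per_group=30, seed=3)
clustering = ss.cluster_domains(groups, resolution=0.5, seed=0)
ari = adjusted_rand_score(groups.meta["planted_group"], clustering.labels)
print(f"two planted populations, n=60 profiles -> "
      f"{clustering.labels.nunique()} Leiden clusters, ARI vs truth = {ari:.2f}")

prog = ss.simulate_progression_profiles(n=60, seed=5)
cl = ss.cluster_domains(prog, seed=0)
root = int(cl.labels.loc[prog.meta["planted_stage"].idxmin()])
traj = ss.trajectory(prog, cl, root_cluster=root)
rho = spearmanr(traj.pseudotime, prog.meta["planted_stage"]).statistic
print(f"planted progression, root cluster {root}: "
      f"Spearman(pseudotime, stage) = {rho:.3f}")

hm = ss.path_heatmap(prog, traj.pseudotime,
                     path_clusters=sorted(cl.labels.unique()), genes=["G01", "G02"])
print(f"path heatmap: {hm.matrix.shape[0]} genes x {hm.matrix.shape[1]} domains,"
      f" columns ordered by pseudotime, values min-max scaled per gene")
print("ARI = 1 and Spearman near 1 mean the pseudobulk pipeline recovers both")
print("the planted populations and the planted progression order.")
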