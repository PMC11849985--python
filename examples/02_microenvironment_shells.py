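"""Stratify the microenvironment into 30-µm shells around detected domains.

Runs detection on the default breast-like tissue, measures the signed
shortest-path distance from the domain boundary over the weighted lattice
graph, slices it into half-open (x, x+30] µm shells, and prints where each
planted marker concentrates.  Also shows the per-domain exclusive outer
sections (contested grids between neighbouring domains belong to nobody).
"""

import spatialshell as ss

spec = ss.breast_like_spec(seed=7)
cells, truth = ss.simulate_tissue(spec, seed=7)
grid = ss.build_grid(cells, pitch=10.0)
mask = ss.median_denoise(ss.detect_pre_domain(grid, ss.MarkerSpec(["CDH1"])))
labeling = ss.segment_domains(mask)
field = ss.compute_distance_field(mask, ss.extract_boundary(mask), pitch=10.0)
shells = ss.stratify_shells(field, width=30.0, lower=-120.0, upper=150.0)

print(f"{cells.n_cells} cells, {labeling.n_domains} domains")
print("per-shell mean counts per grid (density):")
print(f"{'shell (µm)':>16} {'CDH1':>7} {'KRT14':>7} {'CD8A':>7}")
for iv in shells.intervals:
    m = shells.mask(iv)
    if not m.any():
        continue
    row = [grid.gene_image(g)[m].mean() for g in ("CDH1", "KRT14", "CD8A")]
    print(f"({iv[0]:>5.0f},{iv[1]:>5.0f}] {row[0]:7.3f} {row[1]:7.3f} {row[2]:7.3f}")
print("The tumor marker (CDH1) peaks inside (negative shells), the planted")
print("myoepithelial-like boundary marker (KRT14) in (0,+30], and the planted")
print("immune marker (CD8A) in (+30,+60] — the distances they were planted at.")

for level in (0.0, 120.0):
    sections = ss.exclusive_outer_sections(labeling, shells, level=level, pitch=10.0)
    iv = (level, level + 30.0)
    n_total = int(shells.mask(iv).sum())
    n_claimed = int(sum(sec.sum() for sec in sections.values()))
    print(f"exclusive ({iv[0]:.0f},{iv[1]:.0f}] sections: {n_claimed}/{n_total} "
          f"shell grids attributed to a unique domain")
print("Grids inside two domains' expanded rectangles are contested and belong")
print("to no domain's section — at deeper levels the rectangles overlap more.")
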