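"""Detect marker-defined spatial domains on a synthetic tissue section.

Simulates a small Xenium-style section with two planted carcinoma-like
disks, bins the cells onto a 10-µm lattice, applies the marker logic
(CDH1-positive, no negative marker), denoises with the 3x3 majority filter
and segments the mask into individual domains.
"""

import spatialshell as ss

spec = ss.TissueSpec(
    field_size=(900.0, 900.0),
    domains=[ss.DiskDomain((280.0, 280.0), 140.0),
             ss.DiskDomain((650.0, 620.0), 120.0)],
)
cells, truth = ss.simulate_tissue(spec, seed=11)
print(f"simulated {cells.n_cells} cells over {spec.field_size[0]:.0f} µm "
      f"x {spec.field_size[1]:.0f} µm with {len(spec.domains)} planted domains")

grid = ss.build_grid(cells, pitch=10.0)
print(f"expression lattice: {grid.n_cols} x {grid.n_rows} grids at {grid.pitch:.0f} µm")

pre = ss.detect_pre_domain(grid, ss.MarkerSpec(positive_genes=["CDH1"]))
mask = ss.median_denoise(pre, kernel=3)
labeling = ss.segment_domains(mask)
boundary = ss.extract_boundary(mask)

print(f"detected {labeling.n_domains} domains "
      f"(areas in grids: {sorted(labeling.areas.tolist())}), "
      f"{int(boundary.sum())} boundary grids")
print(f"agreement with planted truth (Jaccard): {ss.jaccard(mask, truth.mask):.3f}")
print("A Jaccard near 1 means the marker-thresholded, denoised mask recovers")
print("the planted tumor disks almost grid-for-grid.")
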