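# Methods

## The model

`spatialshell` analyses single-cell spatial omics data (Xenium-style: a
cell×gene count matrix plus cell centroids in µm) through a fixed-pitch
expression lattice. Every cell contributes its counts to the grid square
containing its centroid, under the half-open convention
`[k·pitch, (k+1)·pitch)` with the origin at the minimum coordinate rounded
down to a pitch multiple. The default pitch is 10 µm: coarse enough that a
marker gene's transcripts are reliably sampled per grid, fine enough to
resolve 30-µm microenvironment shells. Grid indices are 0-based; the origin
is stored so lattices can be aligned back to µm coordinates.

**Domain detection.** A grid belongs to the pre-domain mask when the summed
count of the positive marker list is > 0 and the summed count of the
negative marker list is 0 (logical subtraction of the negative-expressing
grid set). One pass of a 3×3 median filter — for a binary mask, a majority
vote over the window, with replicate padding at the lattice edge — removes
isolated false grids and fills isolated holes. Individual spatial domains
are the 8-connected components of the denoised mask, labelled 1..D in
raster order of each component's first grid; the boundary is the set of
domain grids with at least one 8-neighbour in background, with the lattice
border treated as background so truncated domains still close.

**Signed distance.** All grids are nodes of an undirected lattice graph
with 8-adjacency edges weighted 1 (orthogonal) or √2 (diagonal) in pitch
units. The distance of a grid is the shortest weighted path to the nearest
boundary grid, computed by multi-source Dijkstra over the full graph — the
domains are not obstacles — and scaled to µm by the pitch. On an
obstacle-free lattice with one source this is exactly the octile metric
`max(|Δc|,|Δr|) + (√2−1)·min(|Δc|,|Δr|)`. The sign is negative strictly
inside a domain, zero on boundary grids, positive outside.

**Shell stratification.** Distances are sliced into half-open shells
`(x, x+w]` with w = 30 µm over (−120, +150] by default; a grid with µ = 0
falls in (−30, 0] and one at µ = 30 in (0, +30]. Inner sections of a domain
are the negative shells restricted to the domain's own grids (domains are
disjoint, so these are automatically exclusive). Outer shells are shared
space: each domain's claim is its axis-aligned bounding rectangle expanded
by (x+w) µm per side and clipped to the lattice, and the exclusive section
is

    PS_d = P_(x, x+w]  ∩  R_d  \  ⋃_{i<j} (R_i ∩ R_j)

so any grid inside two or more expanded rectangles belongs to no domain's
microenvironment. The expansion uses (x+w) rather than x so the rectangle
geometrically contains the shell it indexes; `expand_by_x=True` switches to
the bare-x expansion. Pairwise intersections are recomputed per level.
Section expression is the unweighted mean count per grid; an empty section
propagates as missing, never as zero.

**Pseudobulk profiles and statistics.** Each domain's profile is the mean
per-grid count of every gene over its grids. Alpha diversity of a profile
(or a single cell) uses the bias-corrected Chao1
`S_obs + F1(F1−1)/(2(F2+1))`, Shannon entropy in bits (base is a
parameter), and the observed-feature count; these delegate to scikit-bio.
Geary's C is computed from its definition,
`C = (n−1)·Σ w_ij (x_i−x_j)² / (2W·Σ (x_i−x̄)²)`, with binary 8-adjacency
weights among the grids of a region as the default weight matrix; the unit
and weights are configurable because the statistic is meaningful for any
symmetric weighting.

**Clustering and trajectory.** Profiles are treated as a small single-cell
experiment: log1p, PCA (50 components by default, clipped with a warning
when the matrix is smaller), a k-nearest-neighbour graph (k = 15), Leiden
community detection, and a 2-D embedding (UMAP default, t-SNE optional;
the embedding never affects labels). PCA uses the full (LAPACK) SVD so
results are exactly reproducible and degenerate inputs are handled.
Trajectories use partition-based graph abstraction over the clusters plus
diffusion pseudotime anchored at a root unit. The paper-style interface
names only a root *cluster*; the root *unit* is chosen deterministically as
the domain nearest the root cluster's centroid in PC space. Multi-sample
integration concatenates profile matrices on the intersection of their gene
panels with sample/patient provenance columns; no batch correction is
applied, so strong sample-level technical shifts will leak into clusters
(see Limitations).

**Microenvironment statistics.** Expression density of a section is total
counts divided by the section's grid count (area-normalised, in counts per
grid); cell-count weighting is deliberately not used because the sections
are geometric objects. Group comparisons fit a GLM of density on section,
group and their interaction — Gaussian family with identity link by
default, Poisson/log available for count-like densities — with the section
coded either ordinally by its interval midpoint (default) or categorically
by dummies; the design matrix is rank-checked and the collinear term is
named on failure. The correlation screen computes the Pearson r between
each gene's section-density profile and a reference gene's profile and
reports the set with r ≥ 0.75 (threshold configurable); zero-variance
profiles yield a missing r and never pass. The omnibus cluster comparison
within a section is a Kruskal–Wallis test with an optional Bonferroni
factor for screening families.

## The synthetic-tissue generator

`synth.simulate_tissue` emulates the input data model at desk scale: cells
are placed by compartment-wise homogeneous Poisson point processes and
transcripts drawn per gene as Poisson counts at compartment-specific rates
(a gamma–Poisson option adds overdispersion). Compartments are defined
around planted disk-shaped tumor domains: the disk interior (tumor,
CDH1-like marker at 20 transcripts/cell), a 20-µm myoepithelial-like
annulus just outside the edge (KRT14-like marker at 5/cell), an immune
shell of stroma at (30, 60] µm Euclidean distance from the nearest edge
(CD8A-like marker at 5/cell), and far stroma. Domain phenotypes plant
downstream effects: *infiltrated* domains express the endothelial marker
(PECAM1-like, 3/cell vs 0.1 baseline) inside the tumor, and *staged*
domains carry a latent stage driving monotone MKI67-up/ACTA2-down
gradients. Thirteen filler genes at a uniform 0.2/cell model uninformative
panel content.

The default study conditions (`breast_like_spec`) are 42 DCIS-scale disks
of radius 150 µm on a jittered 550-µm lattice in a ~3.8 × 3.1 mm field,
with cell densities 0.02/µm² (tumor), 0.015 (ring) and 0.001 (stroma) —
about 80&nbsp;000 cells. The domain radius matters: marker-threshold
detection on a 10-µm lattice carries an irreducible rim uncertainty of
roughly a third of a grid (partially covered edge grids light up
stochastically), so detection accuracy is rim/area-limited; at r = 150 µm
the detected mask agrees with the rasterised truth at Jaccard ≈ 0.955
across seeds. Ground truth is rasterised on the same lattice the gridding
stage builds (a grid is true when its centre lies in a disk), eliminating
off-by-one disputes in tests.

What the generator does **not** model: irregular domain morphology, cell
shapes and segmentation error, transcript-level spatial noise or
misassignment, realistic panel-wide co-expression structure, and spatial
gradients within a compartment. Passing the planted-recovery tests
therefore shows that the pipeline recovers geometry and rates it was
pointed at under clean sampling noise — not that detection thresholds or
clustering parameters are optimal for any real tissue.

Profile-level fixtures (`simulate_profile_groups`,
`simulate_progression_profiles`) plant two marker-block populations and a
60-profile 1-D progression with multiplicative lognormal noise; they test
the clustering/trajectory stage in isolation from the imaging stages.

## Numerical choices

- Shell assignment uses `ceil((µ−lower)/w − ε) − 1` with ε = 1e−9 so exact
  upper bounds (reachable by pure orthogonal paths) land in their closed
  interval despite float error.
- 8-connectivity is used everywhere (components, boundary, distance graph)
  for consistency with the √2 diagonal edges.
- The median filter is applied exactly once; replicate padding makes the
  edge behaviour explicit and is what the oracle tests encode.
- Rectangle expansion in grids is `ceil((x+w)/pitch)` so non-divisible
  pitches still contain the shell.
- Leiden at the default resolution 1.0 can split a ~30-profile noise ball
  into spurious subclusters on a few percent of realizations; harnesses
  that ask for coarse two-population recovery use resolution 0.5, which
  recovered the planted pair on 41/41 scanned seeds. Cluster count is
  non-decreasing in resolution on fixed inputs.
- Geary's C raises on constant fields and edgeless weight matrices rather
  than returning NaN.
- All randomness flows through explicit integer seeds; clustering,
  embedding and pseudotime are bit-reproducible under a fixed seed.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice: the
full tissue pipeline uses the ~80k-cell default section (sub-second),
oracle comparisons use 10–20 random 50×50 or 64×64 lattices against O(V²)
brute-force implementations, the GLM coverage simulation uses 100
replicates of 200 observations, and null simulations use 1000 draws.

## Limitations

- Detection accuracy is bounded by the ~⅓-grid rim bias discussed above;
  thin structures (monolayer epithelium) can fall below the marker-
  sampling threshold at 10 µm pitch entirely.
- Expression density is area-normalised; in tissue where cellularity
  varies strongly across sections, density mixes expression level with
  cell packing (visible in the correlation screen, where uniformly
  expressed genes track cellularity).
- No batch correction is applied in multi-sample integration; the cohort
  harness shows clean phenotype grouping only when sample-level technical
  shifts are absent or mild.
- The exclusive-section formula discards grids contested between expanded
  rectangles globally; dense domain packings lose a growing fraction of
  deep outer shells to contention.
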