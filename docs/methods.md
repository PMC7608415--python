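# Methods

## Model and assumptions

The package rests on three assumptions: (1) the interaction potential of
two cells is a function of the abundance of their ligands and receptors
and of pair-specific affinities; (2) cells with high mutual potential tend
to be spatially close; (3) cells compete for partners because physical
space is limited.  Protein concentration is approximated by mRNA abundance
in TPM, and every multi-subunit complex is assumed pre-expanded into
binary ligand-receptor rows (the bundled "extended" table documents an
all-pairs expansion of complexes into binary rows).

**Affinity.**  For LR pairs k with weight w_k, `A_ij = Σ_k w_k (e_i^{L_k}
e_j^{R_k} + e_i^{R_k} e_j^{L_k})` for i ≠ j; the symmetric second term
covers both cells expressing both molecules; homotypic pairs (ligand ==
receptor) are allowed, the two terms then coincide and are both counted,
as the formula reads.  With no knowledge of per-pair kinetics all weights
default to 1 and are exposed as a column of the LR table.  B2M-containing
pairs are excluded by default because of the gene's housekeeping nature.
The matrix is discretised by keeping each cell's k = 50 strongest
neighbors, union-symmetrised (an edge survives if either endpoint selects
it) so the embedding objective keeps a symmetric P.  Normalisation to
P = A / Σ A happens after discretisation, so P sums to exactly 1 over the
retained edges.  Ties at the k-th value break toward the lower cell index;
runs are fully deterministic.

**Embedding.**  Coordinates minimise KL(P || Q) with the Student-t kernel
q_ij ∝ 1/(1 + d_ij²), by gradient descent with momentum from a uniform
random start inside the R-sided cube.  Two constraints model tissue:
d_ij ≥ r (cells have positive size; r = 1) and |y| ≤ R (bounded space;
R = 50).  Defaults: 1000 iterations, learning rate 200, momentum 0.5
switching to 0.8 at iteration 250, no early exaggeration.  The bound R is
enforced by per-coordinate clipping after every update.  The minimum
distance is enforced by a position-based overlap-resolution pass: after
each gradient step, every pair closer than r is pushed apart symmetrically
by half its overlap (one Jacobi projection per iteration), and the kernel
distance is floored at r so Q stays consistent with the feasible set.  We
chose projection over a purely soft floor deliberately: with a soft floor
the flat kernel exerts no force inside r, so cells with near-identical
affinity profiles stack onto coincident coordinates and within-population
packing becomes tighter than the cross-population contact shell, inverting
colocalization signals.  The projection pass reuses the O(n²) distance
computation the gradient already needs, so the asymptotic cost per
iteration is unchanged.  Cells whose P row is all zero receive no
attractive force, drift under repulsion, and are flagged in the log.
Dimensions 1 and 2 are supported for cord- and sheet-like tissue models.
After optimisation the cloud is centred and PCA-rotated (numpy SVD) so X
captures the most variance, with a deterministic sign convention; rotation
preserves all distances but not the axis-aligned |y| ≤ R box.

**Spatial statistics.**  The working radius is the median distance of each
cell to its 3rd nearest neighbor (nth configurable; results are expected
to be robust between nth = 3 and 5 and this is tested).  Density is the
number of other cells within the radius (inclusive).  Compact structures
use density-peaks clustering: δ_i is the distance to the nearest cell of
higher density under the deterministic ordering (density descending, index
ascending, which resolves ties and makes fully coincident input collapse
to one structure); the global peak takes the maximum pairwise distance;
centers are cells with γ = ρ·δ above mean(γ) + 3·sd(γ) (factor
configurable), with at least one center whenever any cell has positive
density; zero-density cells are "dissociative" (this rule wins over the
minimum-one-center rule in the degenerate all-isolated case).  Connections
are cell pairs strictly closer than the radius; counts are per unordered
cluster pair including self-pairs.  Significance comes from 1000 global
label permutations over all embedded cells with coordinates fixed;
p = (1 + #{null at least as extreme}) / (n_perm + 1) per tail (add-one
smoothing avoids p = 0), BH correction within each tail across all pairs,
and a pair is enriched (depleted) when both its tail p and q fall below
0.05, otherwise "other".

**Contributions.**  A cell pair's affinity is decomposed into per-LR-pair
fractions (they sum to 1 wherever total affinity is positive); a cluster
pair's contribution vector is the unweighted mean over connected cell
pairs, where "connected" here is inclusive (d ≤ T) while connection
*counting* is strict (d < T) — the two conventions are kept as stated for
each statistic.  Zero-affinity pairs inside the neighborhood are skipped
(their decomposition is undefined) and excluded from N.

**Perturbation.**  Knockdown zeroes a gene, overexpression sets it to a
level (default TPM 5000), both across all cells by default with an
optional cluster restriction; depletion removes a cluster's cells.
Adoptive transfer appends donor cells under a new label and wires them to
a target cluster via a reserved pseudo pair (`__pMHC__` at TPM 5000 in
target cells, `__TCR__` at a tunable level in donors, weight 1); pseudo
genes are appended without re-running TPM normalisation, since the edit is
defined as setting absolute TPM values.  The transfer sweep re-runs the
full pipeline per TCR level from the same seed, so differences reflect the
perturbation, not initialization, and reports percent of realised tumor-T
connections (denominator: #malignant × #donors, our definition of the
theoretical maximum), percent of infiltrating donors and percent of
targeted tumor cells, each with linear and logarithmic least-squares R².
Baselines may either include the donors with an inert (level-0) receptor —
which leaves the affinity matrix exactly equal to the pseudo-pair-free one
— or exclude them entirely by running the host alone.  All before/after
comparisons operate on interaction reports, never raw coordinates: the
pseudo-space axes are arbitrary, so only graph-level structure is
comparable across runs.

## Synthetic data

The generator emulates exactly what the pipeline consumes: populations
with per-gene mean TPM-scale levels, log-normal multiplicative noise
(σ = 0.25 by default; scRNA-seq abundances are heavy-tailed), optional
Bernoulli dropout (off by default), TPM renormalisation, and a declarative
truth object naming the wired cluster pairs and their dominant LR pair.
The default benchmark is 3 populations × 100 cells with one planted pair
(mean level 3000) against five decoys (level 20) over 40 background genes
(level 50).  The tumor/transfer benchmark (3 × 60 cells plus 60 donors)
raises the background budget to 2500 per gene so that signal genes land
near 5000 TPM after normalisation: a compressed ~50-gene transcriptome
otherwise inflates every gene's TPM ~100-fold, which would make an
absolute TPM-5000 pseudo-pair artificially uncompetitive.  What the
generator does *not* model: realistic transcriptome breadth, gene-gene
correlation, batch effects, ambient RNA, or tissue geometry — truth is
defined at the affinity/interaction level only.  Passing tests therefore
show the pipeline recovers planted interaction structure through every
stage; they do not validate the biological hypothesis on real tissue.

## Numerical choices and degenerate inputs

Probability sums are asserted to 1 within 1e-9; affinity equals its
brute-force oracle within 1e-9 absolute.  All randomness flows through
seeded `numpy` generators with draws in fixed cell order; identical seeds
give bit-identical coordinates.  All-zero expression columns survive TPM
unscaled with a warning; LR genes absent from the matrix contribute zero
affinity with a coverage warning; an affinity matrix that is identically
zero, an empty LR table after filtering, and unannotated cells are errors.
The optimiser's loss trace is stochastic, so quality checks compare the
mean of the last 50 iterations against the first 50 rather than demanding
monotonicity.  Cells with uniform or absent wiring have degenerate optimal
positions; their pairwise distances vary across seeds while group-level
geometry and the induced interaction map are stable, which is what the
stability tests assert.

## Problem sizes

Tests and the acceptance script run the full pipeline at 300 cells
(benchmark) and 240 cells (transfer sweep) with the standard 1000
iterations and 1000 permutations, sizes at which a full run takes a few
seconds on one CPU; oracle comparisons use n ≤ 20 where exhaustive double
loops and exact permutation enumeration are feasible.

## Known limitations

mRNA is a proxy for surface protein; dropout and LR-table incompleteness
propagate directly into affinity; secreted ligands are treated like
membrane-bound ones (no diffusion or gradient model); pseudo-space
distances are relative, not micrometres; and the permutation null shuffles
labels within whatever cell set was embedded together, which pools donors
in multi-sample designs.
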