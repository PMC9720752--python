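# Methods

This note documents the models, algorithms, defaults and design choices
behind `crossvasc`, stage by stage, in the order the pipeline runs.

## Ortholog mapping from gene trees

Input is a forest of rooted gene trees with species-tagged leaves
(`SPECIES|geneID`, one newick per line). Trees are treated as rooted as
written; unrooted trees (flagged programmatically) are rejected with a
pointer to midpoint rooting rather than silently rerooted, since rooting
changes duplication inference.

**Event labeling.** Each internal node is labeled by the species-overlap
criterion: *duplication* iff at least two of its child subtrees share at
least one species, else *speciation*. Polytomies are handled by pairwise
child comparison. Species overlap is the standard tree-only proxy for
reconciliation against a species tree; it is exact on the package's
simulated forests (where duplications propagate the full species set to
both children) and is verified there against a brute-force enumerator.

**Decomposition.** The labeled tree is cut at every duplication node,
recursively, leaving the maximal subtrees that contain no duplication
node. Equivalently: a node roots a parsed ortho-group iff its subtree is
duplication-free and its parent's subtree is not. The leaves of the groups
partition the tree's leaves. On `((At|g1,Pt|g2),(At|g3,(Pt|g4,Pt|g5)))`
the groups are `{g1,g2}`, `{g3}`, `{g4}`, `{g5}`: cutting the duplication
at the root separates the two cherries' contexts, and the nested `(g4,g5)`
duplication isolates `g3`. Alternative rules that keep sibling context when
cutting a nested duplication would merge `{g3,g4}` or `{g3,g5}`; we cut at
the duplication node itself because it is the only rule that needs no
arbitrary choice of which duplicated child keeps the sibling.

**One-to-one extraction.** A group with exactly one gene from each focal
species contributes that pair; genes of other species in the group are
ignored (adding a third-species leaf can therefore never remove a pair).
Output order and all tie-breaks are lexicographic, so the mapping is
byte-reproducible.

**Extended homolog table.** For gene-ID translation, one-to-one pairs are
merged with an optional many-to-one homolog table (one-to-one wins on
conflict, being the higher-confidence call). When k ≥ 2 source genes share
one target, they receive suffixes `.1 … .k` in lexicographic source order;
sources with no homolog map to their own ID. Translated IDs must be
globally unique; collisions are an error rather than a warning because a
silent merge would sum two genes' counts.

## Synthetic data

The simulator generates the statistical structure the analysis assumes,
with full ground truth.

Per cell *i*: latent time tᵢ ~ Uniform(0,1); library size
Lᵢ ~ LogNormal(ln 3618, 0.3) — the location mirrors a typical per-nucleus
UMI total and the 0.3 log-SD gives the right order of per-cell spread
without modeling capture efficiency explicitly. Clusters are the
equal-width thirds of t (3 per lineage by default), standing in for the
ordered cluster path of a differentiation trajectory.

Per gene *g*, species *s*: counts ~ NB(mean μ, dispersion θ) with
Var = μ + μ²/θ (θ = 2 by default, a typical UMI overdispersion; θ = ∞
degenerates to Poisson), and

  log μ = log Lᵢ + β₀_g + b_{g,s} + f_{g,s}(tᵢ)

with baseline β₀_g ~ Normal(log(1/n_genes), 0.5), species offset
b_{g,s} ~ Normal(0, batch_sd = 0.3) emulating a species/batch effect, and
a smooth profile f drawn from three families (linear ramp, logistic front,
unimodal peak) with amplitude 1.5–2.5 natural-log units and random sign.

Gene classes (largest-remainder apportionment so class sizes are exact):
**conserved** genes share one profile across species; **divergent** genes
get independently drawn profiles, re-drawn until the two noiseless
profiles correlate below 0.3 so the class label is unambiguous (without
the re-draw, two independent monotone profiles agree by chance often
enough to blur the truth the recovery tests measure against); **flat**
genes have f ≡ 0. A configurable fraction (default 10%) of species-B genes
is emitted as two paralog copies with identical means and independent
sampling noise, mimicking lineage-specific duplications.

Defaults — 600 cells per species, 1000 genes split 0.2 / 0.2 / 0.6 — are
the conditions all recovery properties are stated at. Everything is
deterministic given the seed.

What the simulator does *not* model: ambient RNA, doublets, zero inflation
beyond NB sampling, per-cell cycle effects, and any non-smooth temporal
structure. Passing recovery tests therefore demonstrate correctness of the
pipeline's statistics under its own assumptions, not robustness to those
artifacts.

The forest simulator grows trees where internal nodes are duplications
(children inherit the species set) with probability `dup_prob` whenever
the leaf budget allows, else speciations (children partition the set), so
every species assigned to a subtree is realized in it and species-overlap
labeling recovers the constructed events exactly — which is what makes the
forest a usable oracle.

## Preprocessing

- **QC**: keep nuclei with detected-gene count in [1000, 7000], both ends
  inclusive (below: likely ambient-only GEMs; above: likely multiplets).
  Only the detected-gene criterion is used — no organellar-fraction filter,
  appropriate for sorted nuclei.
- **Normalization**: x = ln(1 + c·scale/total), scale 10⁴.
- **HVG**: per-gene variance of normalized expression z-scored within 20
  equal-count mean bins (removing the mean-variance trend); zero-variance
  genes rank last; ties break by gene ID. Default 2000 genes.
- **PCA**: centered, unit-scaled, full SVD; each component's sign is fixed
  by making its largest-magnitude loading positive, so embeddings are
  reproducible bit-for-bit.
- **Clustering**: Euclidean k-NN (k = 20), SNN edge weights as Jaccard
  overlap of self-inclusive neighbor sets pruned below 1/15, Leiden
  (RB-configuration) at resolution 0.5 with a fixed seed. Cells are
  processed in a canonical coordinate-sorted order, which makes the
  partition invariant to input row order; labels are re-numbered by
  decreasing cluster size. k and resolution are config-exposed; no single
  default suits all datasets.
- **Markers / cluster DE**: two-sided Wilcoxon rank-sum on normalized
  expression, one cluster vs rest (or group vs group). The natural-log
  fold change is computed on expm1-backtransformed means with ε = 10⁻⁹.
  Genes failing the detection-fraction (10%) or lnFC (0.25) filter are
  excluded *before* testing — this shrinks the BH universe, mirroring the
  common tooling behavior, and is logged for auditability. P-values are
  exact (full permutation enumeration over midranks, handling ties) when
  both groups have ≤ 8 cells, else the tie-corrected normal approximation
  with continuity correction. BH adjustment is applied within each
  cluster's tested genes. Clusters under 3 cells are skipped.

## Integration

Species B's genes are translated to species A's ID space via the
one-to-one map (species A — the *Arabidopsis*-like reference — keeps its
IDs). Both matrices are restricted to the shared ortholog features plus
any curated markers present in both, z-scored per feature *within*
species (so per-species scale and constant offsets cannot dominate the
joint geometry), and embedded by a joint sign-fixed PCA (30 dims).

Mutual nearest neighbors (k = 15) across species in PC space define
difference vectors a − b. Each anchored B cell averages its own pair
vectors with a softmin Gaussian weighting (bandwidth = its closest pair
distance), so a cell already aligned with an A cell receives essentially
no shift — this avoids the neighborhood-mean bias a flat average over
pairs would introduce. The anchored corrections are then Gaussian-smoothed
over all B cells (bandwidth = median distance to the nearest anchor,
config-overridable) and added to B's coordinates; A is never moved.
Expression matrices are never altered, only the embedding. The mean
same-species fraction among 15 nearest neighbors (0.5 = perfect mixing at
equal sizes) is computed and logged for every run.

This MNN correction stands where the original analysis used an
anchor-based integration tool; the downstream surface (joint clusters
shared across species, trajectories over the joint embedding) does not
depend on which correction produced it, and MNN has a contract each test
can check directly.

## Trajectory inference

A minimum spanning tree is built over cluster centroids (Euclidean
weights; Kruskal with edges sorted by (weight, id-pair) so ties are
deterministic). A lineage is the ordered path from a user-supplied start
cluster to a leaf — the start cluster is a biological choice (the
procambium-like cluster in the motivating analysis), not inferred.
Pseudotime is the arc-length coordinate of each cell's clamped orthogonal
projection onto the piecewise-linear curve through the lineage's ordered
centroids; cells equidistant to two segments assign to the earlier one.
An optional principal-curve-style refinement (project → re-estimate
vertices from equal-count arc blocks → refit) is available but off by
default: on the simulated lineages the plain centroid polyline already
recovers latent time at Spearman ρ ≈ 0.99, and the refinement adds
iteration-order dependence.

## Trajectory comparison

**Association test.** Per gene, raw counts over the lineage's cells are
regressed on a cubic B-spline basis of pseudotime (df = 6, knots at
pseudotime quantiles — df 6 matches the common default of spline-based
trajectory DE tools) with a log library-size offset. The family is
negative binomial with a per-gene dispersion moment-estimated from a
Poisson fit of the full model (clipped to [10⁻⁸, 100]); full and
intercept-only NB fits are compared by a likelihood-ratio test, χ² with
df = basis dimension. Genes detected in < 1% of lineage cells are reported
NA; non-convergent fits are flagged and excluded from the BH universe.
Significance is BH FDR ≤ 0.01. Testing raw counts with an offset (rather
than corrected values) keeps the NB likelihood honest; the moment
dispersion is slightly conservative for strongly DE genes and accurate
for null genes, which is the direction that protects error control. At
least 50 pseudotime-assigned cells are required.

**Binning.** Cells are sorted by pseudotime (ties by cell ID) and split
into 30 contiguous blocks; when N mod 30 = r > 0 the first r bins take one
extra cell, so sizes differ by at most 1. Bins are computed per species on
that species' own cells and normalized expression, after the (joint)
pseudotime.

**Correlation and classification.** For genes DE in both species, Pearson
correlation of the two 30-bin mean-expression profiles; profiles are not
re-scaled (Pearson is affine-invariant). Significance of positive
association via the t statistic with n_bins − 2 = 28 df, one-sided — a
circular-shift permutation alternative is config-gated; BH across genes
within the lineage. A gene passes when r ≥ 0.5 *and* FDR ≤ 0.01.
Verdicts: **conserved** (DE in both, correlation pass),
**common_not_correlated** (DE in both, pass failed or correlation
undefined), **species_specific_A/B** (DE in one), **not_DE**. Genes
without a cross-species match (e.g. paralog copies kept under their own
IDs) are reported separately rather than silently dropped. Zero-variance
profiles yield NA and leave the BH universe.

## Numerical and degenerate-input policy

Exact identity or contract errors, never silent coercion: duplicate IDs,
non-integer counts, zero-total cells, overlapping DE groups, fewer cells
than bins, constant pseudotime, and empty feature intersections all raise.
All orderings that could depend on hash or input order (pair lists, suffix
numbering, MST ties, bin ties, HVG ties) are made deterministic by
explicit lexicographic tie-breaks.

## Problem sizes used in tests

Recovery properties run at the simulator's default conditions (600 cells
per species, 1000 genes); the tree-parsing oracle runs on 200 trees of up
to 12 leaves over 4 species; supporting unit tests use smaller fixtures
chosen so each check isolates a single contract. The full suite and the
acceptance script each complete in about a minute on one CPU.

## Known limitations

- Species-overlap duplication labeling over-calls duplications when gene
  trees have topological errors; real OrthoFinder-style reconciliation
  against a dated species tree is out of scope (trees are consumed, not
  inferred).
- The MNN correction aligns location, not shape: strongly species-specific
  subpopulations can be pulled toward the reference cloud.
- The piecewise-linear pseudotime is rank-faithful but compresses arc
  length near high-curvature turns; branch-point statistics and RNA
  velocity are out of scope.
- The NB-spline LRT uses a plug-in dispersion; no empirical-Bayes
  shrinkage across genes is applied.
- Conservation verdicts inherit binning granularity: with 30 bins,
  temporal shifts smaller than ~1/30 of the trajectory are invisible.
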