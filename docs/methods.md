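# Methods

## Model and procedure

`lncprior` ranks candidate disease lncRNAs by propagating known disease
genes over a weighted gene–lncRNA association network and pooling the
propagated scores across diseases through phenotype similarity.

**Probe re-annotation.** Exon-array probes are assigned to lncRNA genes by
strict interval rules on 0-based half-open coordinates: a probe must fall
completely inside at least one exon of exactly one lncRNA and must not
overlap any protein-coding gene's genomic span (span, not just exons — the
stricter reading, which also removes probes in coding introns). Probes
contained in exons of two distinct lncRNAs are discarded as ambiguous. An
lncRNA is retained only with ≥ 4 surviving probes. Intensities are then
log2-transformed per probe, averaged per lncRNA, and quantile-normalized
across samples, in that fixed order. Whether log2 should precede or follow
probe averaging is genuinely underdetermined; log2-first was chosen and is
part of the contract (the two orders differ because the mean does not
commute with the log).

**Co-expression network.** Per disease, Pearson correlation is computed
for all gene–gene and gene–lncRNA pairs; a pair is an edge iff its
co-expression score strictly exceeds 0.8 (gene–gene) or 0.7 (gene–lncRNA).
The score is |r| by default; whether thresholding should be signed is an
open choice, and `signed=True` switches to raw r. lncRNA–lncRNA pairs are
never edges. Zero-variance features are skipped with a warning since their
correlation is undefined. Correlations are computed blockwise
(`block_size`, default 2000 rows) to bound memory; results are independent
of the block size.

**Pan-cancer integration.** Disease edge sets are unioned; the weight of a
pair is the fraction of disease types in which it is an edge (k/n). The
fraction — rather than the raw count — keeps co-expression weights on the
same [0, 1] scale as the protein-interaction probabilities the walk also
consumes. Protein–protein interactions (scores pre-normalized to [0, 1],
e.g. STRING combined scores divided by 1000) are merged by the max rule:
a dual-source pair keeps the stronger evidence, so merging never lowers a
weight and never removes an edge. Nodes seen only in the PPI enter as
gene-type. Multiple expression studies of one disease type should be
concatenated sample-wise before correlation, so the frequency counts
disease types, not studies.

**Random walk with restart.** The weighted adjacency is column-normalized
(walking *to* a node proportional to incident edge weight). The walk

p ← (1 − r)(W p + m p₀) + r p₀

iterates from p₀ (uniform over the seed genes) until the L1 change falls
below `tol`; m is the probability mass on isolated ("dangling") columns,
which is redistributed to the restart vector so Σp = 1 exactly at every
step. The restart probability r = 0.7 is the conventional choice for
disease-gene propagation; the spectral radius of (1−r)W is ≤ 0.3, so the
iteration contracts fast (≈ 25 iterations at tol = 1e-10) and the fixed
point equals the closed form p = r(I − (1−r)W̃)⁻¹p₀, which the tests use
as an independent oracle. Non-convergence within `max_iter` (default 1000)
raises with the residual rather than returning a half-converged vector.

**Phenotype integration and ranking.** With S the disease × node matrix of
walk scores and P the symmetric disease × disease phenotype-similarity
matrix (entries in [0, 1], diagonal 1; absent diagonals are set to 1 on
read), the integrated score is s_ik = Σ_j P_ij s_jk, including j = i.
Candidates of the requested node type are ranked descending by s_ik with
ties broken by node id, so rankings are deterministic and invariant to the
order diseases are supplied in.

## Evaluation protocols

* **ROC/AUC** — the Mann-Whitney rank statistic (positive-over-negative
  pairs, ties ½), with the curve from scikit-learn on the same scores; the
  trapezoidal area of the curve equals the rank AUC. Negatives for lncRNA
  evaluation are all lncRNA nodes not listed positive for that disease;
  the headline average AUC is the unweighted mean over diseases.
* **Gene LOOCV** — each seed is withheld in turn; the withheld disease's
  walk and the full cross-disease integration are recomputed (no score
  patching), and the held-out gene's rank among gene-type non-seed nodes
  is recorded. Negatives are genes never used as that disease's seeds;
  each held-out gene is compared against the negatives of its own re-run,
  and the pooled AUC is ΣU_g/(n_pos·n_neg). Diseases with a single seed
  are skipped with a logged reason. The LOOCV ROC curve is the exact
  rank-based step curve (jump points duplicated), so its trapezoid equals
  the pooled rank AUC.
* **Phenotype ablation** — `exclude` replaces P by the identity;
  `permute` shuffles the off-diagonal entries jointly over symmetric
  positions, preserving symmetry and the diagonal, so every permuted
  matrix is still a valid similarity matrix. Only integration is rerun
  (the walks do not depend on P).
* **Random-seed control** — every disease's seeds are replaced by an
  equal-size uniform draw from a non-disease gene pool (disjoint from all
  true seeds); the empirical p-value uses the +1 correction,
  p = (#{null ≥ true} + 1)/(n_reps + 1), so it is never exactly zero.
* **Disease-subset sweep** — integration is restricted to a random subset
  of diseases always containing the evaluated one; size 1 coincides with
  `exclude`, size N with the full pipeline.
* **Leave-disease-out** — s_ik = Σ_{j≠i} P_ij s_jk; a disease with zero
  similarity to all others yields all-zero scores and a warning.

All stochastic protocols take an explicit rng seed and are bit-reproducible.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, with
a closed-form handle for testing. Members of a planted module share a
per-sample latent factor: x = √ρ·z + √(1−ρ)·ε, so the expected pairwise
Pearson correlation is exactly ρ (verified by Monte Carlo in the tests).
Defaults: 6 diseases in two similarity blocks of three, 500 genes, 200
lncRNAs, 60 samples per disease, one 30-member module per disease (5 seed
genes, 8 planted risk lncRNAs, 17 filler genes), ρ = 0.9, noise SD 1,
within-block similarity 0.8, between-block 0.1.

Each disease's seeds come from its own module only, while its positive
list is the union of the planted lncRNAs of *all* its block's modules
(phenotypically similar diseases sharing mechanisms). A disease's own
seeds therefore recover only a third of its positives; the rest are
reachable only through phenotype integration with its block siblings.
This is what makes the ablations informative rather than vacuous: with
self-sufficient seeds, excluding or permuting P would change nothing.
PPI edges are strong (U(0.7, 1)) within modules and weak (U(0.1, 0.4))
between random gene pairs, so the max-merge rule is exercised in both
directions. At a fixed rng seed every emitted file is byte-identical.

What the generator does **not** emulate: array-specific artifacts (probe
GC bias, batch effects), heavy-tailed expression, dependence between
background features, realistic network degree distributions, or incomplete
and biased curation of known genes. Passing on the benchmark shows the
machinery is correct and the integration logic behaves directionally as
intended; it does not certify performance on real tumor compendia. A
small, fully hand-enumerated probe fixture (deterministic intensities,
every filter rule exercised) covers the re-annotation path.

## Numerical choices

* Quantile normalization maps each column onto the vector of row means of
  the column-sorted matrix. Ties are assigned in stable input order by
  default, which guarantees the defining property that every column ends
  with the identical multiset of values; a limma-style `ties="average"`
  variant (tied entries share the mean of their rank positions' reference
  values) is available but breaks that exact multiset identity when tie
  patterns differ across columns, which is why it is not the default.
  Missing values are rejected at read time.
* Thresholds are strict (> 0.8 / > 0.7); correlations use ddof = 1.
* RWR: tol 1e-10 (L1), restart 0.7, uniform p₀ over seeds.
* Empirical p-values: +1 correction.
* Rank ties anywhere: lexicographic node id.
* Degenerate inputs fail loudly: empty seed sets, seeds absent from the
  network, non-gene seeds, malformed intervals (start ≥ end, named in the
  error), nonpositive intensities before log2, asymmetric or out-of-range
  phenotype matrices, PPI scores outside [0, 1], duplicate disease ids.

## Problem sizes used in the reported runs

The acceptance script runs the default benchmark with 100 phenotype
permutations, 200 random-seed draws and 50 repetitions per subset size
{2, 4, 6} — sizes at which the Monte-Carlo error is far below the planted
effect sizes while the whole script completes in seconds. The test suite
additionally checks the walk against a dense linear solve on 100 random
graphs of up to 50 nodes and ROC against exhaustive pair counting on 100
random score sets.

## Known limitations

* Edge weights conflate co-expression frequency and interaction
  probability on one [0, 1] scale; the max rule is a pragmatic, not a
  probabilistic, combination.
* Column normalization makes hub nodes absorb less mass per incident edge;
  row normalization would give a different (also defensible) walk. The
  choice is fixed and documented rather than exposed.
* The per-disease walk ignores disease-specific edge weights: one shared
  pan-cancer network serves all diseases, as in the original design.
* LOOCV pools per-run comparisons; it is not a single pooled score vector,
  and the two differ in the presence of heavy score ties.
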