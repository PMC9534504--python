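# Methods

This note documents the models, parameters and numerical choices behind
`regudyn`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic data model

Counts are simulated per gene *g* and cell *c* as negative binomial with
mean `μ_gc = base_g · s_c · β^{active}` and dispersion θ (gamma–Poisson
mixture; variance `μ + μ²/θ`, default θ = 2, a typical scRNA-seq
over-dispersion level). Gene baselines `base_g` are gamma-distributed
(shape 2, scale 1) and cell library-size factors `s_c` lognormal
(μ = 0, σ = 0.3). Each TF is ON in a cell with a Bernoulli probability set
per age group; when ON, the TF's own mean and the means of its *responsive*
targets are multiplied by the effect size β (> 1 required; default 4, a
strong but realistic fold change that gives coexpression inference a
detectable signal at a few hundred cells). Rewiring is expressed as
per-group responsive-target subsets: every planted edge exists globally in
the ground truth, but acts only in the groups where the target is listed as
responsive, which is how a regulon can be large in adults and shrunken in
old cells without changing the gene universe.

Two marker genes are mutually exclusive across the two simulated cell
types (high mean 60 vs low mean 0.05), and doublets are spiked as
element-wise sums of one random parent per type, `floor(rate · n_cells)`
of them, preserving count integrality. The motif prior is derived from the
planted edges with independent false-negative (per planted edge) and
false-positive (per non-edge) corruption.

What the generator does **not** model: transcriptome-wide gene–gene
covariance beyond the planted regulons, batch effects, ambient RNA, UMI
collisions, or continuous per-cell TF activity levels. Passing the planted
benchmarks therefore shows that the statistical machinery is implemented
correctly and has power under idealized dropout-free regulation, not that
the pipeline is robust to every artifact of real tissue data.

## Consensus GRN inference

Each run regresses each non-TF gene's normalized expression on all TF
expressions with a seeded randomized tree ensemble (default: extremely
randomized trees, 10 trees, depth 5, √p features; a stochastic
gradient-boosting learner is available via `learner="gbm"`). The per-TF
split-importance total is the importance metric (IM); the top
`top_k_per_target` (default 50) positive-IM pairs per target are emitted.
Runs subsample 500 cells without replacement, which both bounds the fit
cost and supplies the run-to-run variability that the retention filter
needs — with few TFs and a generous `top_k`, lowering `top_k_per_target`
(e.g. to 1) is what makes the retention filter discriminative, because only
consistently top-ranked regulators recur across runs.

Consensus keeps a (TF, target) pair iff it appears in at least the
retention fraction of runs — inclusively, so 16 of 20 runs survives a 0.8
threshold — and averages IM only over the runs where the pair appeared
(left-outer-join semantics; absences are never imputed as zeros). The
default `n_runs` is 20 to keep desk-scale experiments fast; production
analyses of real tissue conventionally use 100.

Motif pruning drops edges without motif support in any window, removes TFs
annotated with fewer than 2 motifs entirely (single-motif annotations are
where mis-annotated non-TFs hide), and discards regulons below
`min_regulon_size` (default 10; prevents one-gene regulons from polluting
network statistics). Consensus precedes pruning.

## Activity scoring and binarization

For each cell, genes are ranked by descending normalized expression; ties
are broken by a seeded random permutation, making scores reproducible
without biasing toward gene index order. With `k = ⌈top_fraction ·
n_genes⌉` (default top_fraction 0.05), the raw score is the sum over
`i = 1..k` of the number of regulon genes in the top *i* ranks, normalized
by its maximum (all regulon genes at ranks 1..|R|), so scores live in
[0, 1] and are invariant to monotone transforms of a cell's expression.
An exhaustive step-curve enumeration serves as the oracle in the tests.

Binarization fits 1- vs 2-component Gaussian mixtures to each regulon's
AUC distribution (BIC selection); the threshold is the posterior-equality
crossing between the two component means, found by bisection on the
weighted density difference, with the weighted midpoint as fallback if the
densities do not cross between the means. Unimodal regulons (or those with
fewer than 20 cells) fall back to the 99th AUC percentile, so a regulon
without bimodal evidence is conservatively called OFF almost everywhere;
constant distributions are all-OFF because the ON rule is a strict
inequality.

## Network and dynamics

Graphs keep exactly `⌈(1 − q)·N⌉` edges with the highest mean IM
(default q = 0.85, the top 15%); ties break lexicographically by
(TF, target) so the survivor set is deterministic, and a 10⁻⁹ rounding
guard absorbs floating-point noise in the count. Betweenness centrality is
computed on the undirected skeleton (TF→gene links are treated as
symmetric connectivity, matching how hub status is read off such graphs)
and normalized by `(n−1)(n−2)/2`.

Temporal dynamics: per TF, regulon sizes across ordered age groups are
converted to ratios against the youngest group with a pseudocount of 1 on
numerator and denominator (tolerates size-0 baselines), z-scored per row,
and clustered with fuzzy c-means (fuzzifier 2, 100 seeded restarts, hard
assignment by maximal membership; implemented in `_cmeans.py` since no
fuzzy-clustering routine ships with the scientific Python stack).
Zero-variance rows are labelled `"flat"` and excluded — a TF whose regulon
never changes has no temporal family.

## Trajectory abstraction

The binary regulon matrix feeds a union-of-kNN graph (k = 15) under
Jaccard distance — natural for sparse binary states; Hamming is available.
Distance ties resolve by ascending cell index (stable sort). Leiden
community detection (RB-configuration quality, resolution 0.4, seeded)
partitions the cells; labels are renumbered by decreasing partition size.
Inter-partition connectivity is `c_ij = min(1, e_ij / E_ij)` with
`E_ij = m · 2 n_i n_j / (n(n−1))` — observed kNN edges against the
expectation under random edge placement.

Path extraction thresholds the connectivity matrix at `min_connectivity`
and reduces each surviving component to its maximum-connectivity spanning
tree before reading root→leaf paths. Two numerical realities drive this
design. First, measured connectivities between adjacent partitions of
well-separated populations land in roughly 0.01–0.3, so the threshold
default is 0.01 (the same default the established graph-abstraction
toolkit uses for displaying its abstraction); a higher cutoff routinely
isolates the root. Second, abstraction graphs over more than a handful of
partitions are cyclic and then contain no degree-one nodes at all, so a
literal "leaves of the thresholded graph" rule degenerates to the trivial
root path; the spanning-tree reduction keeps the strongest transitions and
always yields leaves. The root is the partition with the highest fraction
of cells from the configured youngest group (ties: larger partition).
Modulation along a path applies Fisher's exact test to each TF's ON/OFF
counts in consecutive partitions, BH-adjusts across TFs within each pair,
and calls up/down only when the adjusted p < α (0.05) **and** the
ON-fraction change is at least `min_delta` (0.3).

The trajectory benchmark simulates aging as a *continuum*: nine fine
stages mapped to infant/adult/old, with "ordering" TFs whose ON
probability declines linearly across stages (the maturation gradient that
makes neighbouring stages adjacent in kNN space) and three group-specific
programs whose ON probability steps by 0.6 between their own group and the
rest. Discrete, equally-separated blobs are not a useful benchmark here:
their abstraction is an equilateral triangle with no readable ordering,
which is also not how aging tissue behaves.

## QC details

Mitochondrial genes are recognized by the `is_mito` annotation or a
configurable name prefix (default `MT-`). The gene filter (detected in ≥ 3
retained cells) runs after the cell filter, so the QC report is
unambiguous; per-filter removal counts attribute each removed cell to
every rule it violates. Doublet thresholds are fit independently per study,
and a configurable set of age groups (e.g. infants, whose transcriptomes
are atypical) can be exempted from this one filter. The marker test is the
two-sided Wilcoxon rank-sum: exact when both groups have ≤ 25 cells and no
ties, normal approximation with tie correction otherwise; effects are log2
fold changes of de-logged group means with a 10⁻⁹ pseudocount.

## Problem sizes

The test suite and the acceptance script run the consensus chain at
20 TFs × 20 targets × ~1000 cells × 20 runs, the trajectory benchmark at
990 cells × 36 TFs, and the remaining checks at a few hundred cells —
sizes at which every planted structure is comfortably identifiable while a
full run stays in the low minutes on a single CPU.

## Known limitations

- The IM is a relative, learner-dependent quantity; absolute IM values are
  not comparable across learners or `top_k` settings, only rankings are.
- The unimodal binarization fallback (99th percentile) always calls ~1% of
  cells ON even when a regulon is genuinely inactive everywhere.
- Connectivity saturates at 1 by construction; heavily mixed partitions
  are indistinguishable beyond that point.
- Fuzzy c-means assumes clusters of comparable spread in z-score space;
  strongly imbalanced family sizes can merge under k = 6.
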