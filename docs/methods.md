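# Methods

This note documents the statistical procedures, the synthetic-data model,
the default parameters, and the design decisions behind `ornstage`.  It is
the place to look when a default seems arbitrary or a behavior surprising.

## Normalization and quality control

All expression values are log2(CPM+1), computed per cell from the working
counts: CPM_g = 1e6 · count_g / total.  Zeros map to zero, so sparsity is
preserved, and per cell Σ_g (2^value_g − 1) = 1e6 exactly — a property the
test suite asserts.  Normalization refuses zero-total cells by raising with
the offending cell names: silent dropping would mask upstream errors.

For nuclei the working counts are exon + intron (pre-mRNA carries real
signal in nuclear transcriptomes); for whole cells, exon only.  The
`merge_layers` policy is recorded per cell, and a documented switch applies
the depth rule to exon-only counts instead.

Cell quality requires both (i) ≥ 50,000 uniquely mapped reads and (ii) at
least two of the five pan-neuronal markers (*elav*, *brp*, *CadN*, *nSyb*,
*Syt1*) at log2(CPM+1) ≥ 2.  All threshold comparisons are inclusive (≥) as
printed; the dataset-level "expressed receptor" rule is the one deliberate
exception (strictly more than five positive cells).  Cell-identity
filtering removes cells expressing any auditory-neuron gene (*iav*,
*nompC*, *CG9492*, *CG10186*, *fd3F*) at the marker threshold and, at the
stages where the rule applies (early pupal and adult by default),
*acj6*-negative cells.  The QC report exposes counts at each sub-step
rather than a single headline number, because the order of the published
sub-filters is ambiguous.  Gene symbols are matched case-sensitively
(FlyBase symbols are case-meaningful).

## Differential expression

Cluster-vs-rest tests use the Mann-Whitney U statistic on log2(CPM+1)
values.  The test is **one-sided (cluster > rest)** by default: the
downstream use of the gene lists is marker discovery, and markers are genes
*high* in a cluster.  A two-sided alternative is available via the
`alternative` argument; two-group comparisons for enrichment hand-off are
two-sided.

Tie handling: when both groups have ≤ 8 observations the p-value comes from
exhaustive permutation enumeration (exact even under ties); otherwise the
tie-corrected normal approximation with continuity correction is used.
Genes constant across both groups are assigned p = 1 — no evidence, never
a division-by-zero artifact.

Multiple testing: Benjamini-Hochberg within each cluster's test series
(genes), DE at adjusted p < 0.01.  The BH family is per cluster because the
per-cluster DE sets are what the matching stage consumes.  Two-group lists
use Bonferroni at p ≤ 1e-5 and are ranked by fold change
log2((mean_A + 0.1)/(mean_B + 0.1)); the 0.1 pseudocount is part of the
published definition and is kept verbatim.

## Clustering

The feature set for dimensionality reduction is the union of the reference
stage's per-cluster DE genes and the known sensory receptors, restricted to
genes present in the matrix.  The reference stage (the one with maximal
transcriptomic diversity, the middle stage by default) is clustered first
on overdispersed genes to obtain those DE sets — a two-pass bootstrap.
Overdispersion is the standard binned recipe: variance/mean per gene,
z-scored within 20 equal-count mean-expression bins, ties broken
lexicographically.  The bootstrap pass uses the top 1,000 genes (`n_hvg`):
with flat dropout noise, a 500-gene pool captures too few true markers for
the density clusterer to lock on, while 1,000 is robust across seeds; the
definitive second pass always uses the DE + receptor feature set.

Clustering itself is HDBSCAN (min_cluster_size = 6, min_samples = 4) on
principal-component scores (20 PCs by default, full SVD for determinism).
Clustering in PC space rather than the 2-D embedding keeps the cluster
geometry honest; an embedding-space option exists.  Cells the density
clusterer cannot assign are labelled −1 and excluded from profiles, DE, and
matching.  UMAP/t-SNE embeddings are available for visualization and are
deterministic under a fixed seed.  The clusterer is a pluggable stage: any
per-cell labelling (e.g. from an external neural-network clusterer) can be
fed to the downstream stages in its place.

## Receptor analysis

A receptor is "on" in a cell at log2(CPM+1) ≥ 3; co-receptors (Orco, Ir8a,
Ir25a, Ir76b) are excluded from per-cell receptor counting by default
because they are broadly expressed partner subunits, not type identifiers.
The co-expression chord table counts unordered pairs per cell — a
three-receptor cell contributes all three pairs — matching a chord
diagram's edge semantics.  Co-receptor co-expression analyses use the
stringent cutoff log2(CPM+1) ≥ 5.  Receptor–receptor association is plain
Pearson correlation across cells, with zero-variance pairs reported as
missing rather than zero.

## Cluster annotation and cross-stage matching

**Receptor-based annotation**: a receptor is cluster-specific when strictly
more than 50% of its positive cells fall in one cluster AND more than five
positive cells lie in that cluster.  Both knobs are configurable — the
published analysis shows dot plots but states no numeric rule, so the rule
here is an explicit, documented operationalization.  Clusters hosting
receptors of several types get compound labels joined by underscores.

**Marker-rule annotation**: a rule (required genes with thresholds,
optional forbidden genes) that fires in exactly one cluster assigns its
label; multi-cluster firings are reported as ambiguous and assign nothing.

**Automatic matching**: per-cluster DE gene sets from two stages are
compared with the Jaccard index J(X, Y) = |X ∩ Y| / |X ∪ Y|.  For every
cluster the best-scoring partner at the other stage is computed in both
directions; mutual best hits are two-way matches, one-directional best hits
are one-way matches.  One-way matches are only reported for stage pairs
profiled with the same technology (pupal–pupal); pupal–adult pairs forbid
them, since every cluster has a one-way match by construction and the
technology shift makes those unreliable.  Argmax ties are never broken
silently — tied clusters are reported and left unmatched, because silent
tie-breaking would fabricate matches.  J of two empty sets is defined as 0
(no evidence of similarity) with a warning.

Cluster-level transcriptome similarity is Pearson correlation between mean
log2(CPM+1) profiles over a DE gene set.  Dendrograms use average-linkage
agglomeration on Euclidean distances between mean profiles (the linkage the
cited clustermap tooling defaults to; only the metric is stated in the
source analysis) and serialize to newick.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Types and stages** — `n_types` neuron types shared across ordered
  stages; default 20 types, three stages (two pupal cell stages, one adult
  nucleus stage), 30 cells per type per stage (a desk-scale version of the
  few-thousand-cell study design).
* **Receptor codes** — each type owns 1 (or, for a `multi_receptor_fraction`
  of types, 2–3) receptor genes, sampled without replacement so codes are
  disjoint; a `linked_pair` flag plants one two-receptor type even at
  multi-fraction zero, mimicking genomically linked receptor pairs.
  Receptors are highly expressed when on (`receptor_log_fold` = 7 log2
  units over the baseline scale) and silent otherwise.
* **DE programs** — each type has `n_de_genes_per_type` (default 50) planted
  marker genes: near-silent outside the type (`de_off_scale` = 0.05 of the
  baseline mean) and elevated to baseline_mean · 2^`de_log_fold` (default
  fold 2.0) within it.  A `de_turnover` fraction (default 0.2) of each
  type's DE genes is stage-specific; the rest form the cross-stage core
  that matching relies on.  The on/off character matters: under flat
  per-entry dropout, a modest fold on top of an already-high baseline is
  provably swamped by dropout noise in log space, whereas marker-like
  on/off genes — which is what type-specific genes in real antennal data
  look like — leave the planted types cleanly separable.
* **Noise** — counts are negative-binomial (gamma-Poisson, shape
  `dispersion` = 2) around depth-scaled program means; per-cell depth is
  uniform on 100k–1M reads (the study sequenced to ~1M reads per cell);
  every entry is then zeroed independently with probability `dropout_rate`
  (default 0.2).
* **Exon/intron split** — binomial per entry with modality-specific intron
  probability (0.105 for cells, 0.30 for nuclei, matching the observed
  contrast between ~10% intronic reads in cells and ~26–33% in nuclei)
  rather than a transcription-kinetics model.
* **Contamination** — ambient genes (Obp-like, mitochondrial-like) are
  added as independent Poisson counts to nucleus transcriptomes only,
  mimicking contamination picked up during nucleus isolation.
* **Doublets** — a `doublet_rate` fraction of cells (default 0.02,
  "infrequent") is replaced by the gene-wise sum of two same-stage
  transcriptomes; flags are recorded in the ground truth.
* **Off-target cells** — optional auditory-like (acj6-negative) cells per
  stage for exercising the identity filters.

What the generator does **not** emulate: batch effects beyond plate labels,
expression-dependent dropout (real dropout hits weakly expressed genes
preferentially; here it is flat), UMI chemistry, gradual receptor onset
during development (planted receptors are on at every stage), correlated
gene programs within a type, and continuous developmental trajectories.
Passing the recovery tests therefore demonstrates that the pipeline's
logic is correct under the assumed data model — not that it would achieve
the same recovery on real antennal data, where types are less cleanly
separated and annotations rely on external knowledge.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale: the
recovery conditions use 20 types x 2 stages x 30 cells (1,200 cells, 2,000
genes), the doublet experiment 1,000 cells, the null-calibration experiment
750 cells x 1,000 genes — sizes chosen so a full from-scratch rerun of every
quantity completes in about a minute while keeping every per-type count
(~24–30 cells after QC) comfortably above the density clusterer's
min_cluster_size.  All randomness flows through explicit integer seeds
(NumPy `default_rng`); identical configuration and seed reproduce outputs
bit-for-bit, and the pipeline stamps every output file with the tool
version and a configuration hash.

## Known limitations

* The exact-enumeration Mann-Whitney path is quadratic-exponential and
  capped at 8 + 8 observations; beyond that the normal approximation is
  used even though moderately small groups might still benefit from exact
  enumeration.
* `annotate_by_receptor` assigns a receptor wholly to the cluster holding
  the majority of its positive cells; receptors genuinely split across two
  clusters (e.g. one type divided by the clusterer) yield no label rather
  than a shared one.
* The Jaccard matcher consumes whatever DE sets it is given; if two stages'
  DE procedures differ in power, the asymmetry propagates into the match
  scores.  The pipeline always uses the same DE procedure at every stage.
* Dendrogram leaf order is scipy's default; only topology and heights are
  contractual.
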