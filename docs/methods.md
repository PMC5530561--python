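# Methods

This note documents the models, defaults, and design decisions behind
`quantmeta`, and what the synthetic studies it ships with do and do not
demonstrate.

## Abundance estimation

Species abundance uses only paired-match genome hits. The estimator is
a single-pass partition: unique-read abundance Ab(U) = (unique reads)/l
is computed first, then every multi-mapping read contributes Co_s/l_s
to each candidate genome s, with Co_s the candidate's share of unique
abundance among the read's candidates. There is no iterative
re-estimation: Co is computed once from the global unique abundances.
Reads multi-mapping to more than two genomes use the same normalization
over all candidates. A multi-read whose candidates all have zero unique
abundance carries no information under this weighting; it is dropped
and counted in a diagnostics object (`AbundanceDiagnostics`) rather
than spread uniformly, since a uniform split would invent abundance for
genomes with no independent evidence.

Gene abundance relaxes read qualification because genes are shorter
than genomes: a pair counts toward a gene when both ends map within it,
or when one end maps within it and the mate's implied position under a
fixed insert (default 800 bp, configurable) lies outside the gene span.
Hit tables carry no orientation, so "outside" is tested symmetrically:
match start + insert past the gene end, or match end − insert before
the gene start. All tabular coordinates are 0-based half-open.

Properties maintained by construction and enforced in tests: per
multi-read Co weights sum to 1 (or 0 if dropped); abundances are linear
in read counts; with no multi-mapping the estimator equals reads/length
exactly.

## Rarefaction and alpha diversity

Richness is compared across samples after uniform subsampling of reads
without replacement; the production default depth is 9,000,000 reads,
and synthetic fixtures use proportionally smaller depths through the
same config field. Detection after rarefaction is ≥ 1 assigned read
(the alternative, an abundance floor, is not used — the read-count
reading is the natural one for subsampled data). Shannon diversity uses
the natural log; "Simpson" is reported in the Gini–Simpson form
1 − Σp². For matrices that no longer carry per-read identity, the
diversity table offers a multinomial count-draw surrogate at a chosen
depth.

## Differential abundance

A feature is discarded only when its group-level statistic (median by
default) is below the floor in **both** groups; the gene preset floors
medians at 1e-7 with q < 0.001, the cluster preset floors at 1e-8 with
q < 0.0005, KO groups use q < 0.005. A second "results" preset (mean
floor 1e-7, q < 1e-4) is exposed because both filter variants are in
circulation for gene markers; neither is privileged by the code.

The rank-sum test enumerates the exact permutation null (mid-rank ties)
when the smaller group has ≤ 10 samples and otherwise uses the
tie-corrected normal approximation with continuity correction
(delegated to `scipy.stats.mannwhitneyu`). Features constant across all
samples get p = 1. Direction is assigned by comparing group medians.

q-values follow Storey's procedure: π₀(λ) = #{p > λ}/(m(1 − λ)) over
λ ∈ {0.05, …, 0.95}, smoothed by a cubic spline and evaluated at
λ = 0.95, clipped to (0, 1]; q is the step-up transform π₀·m·p_(i)/i
made monotone. Fewer than 10 p-values, or an explicit request, falls
back to Benjamini–Hochberg (π₀ = 1). KEGG aggregation assigns each gene
to its highest-scoring orthology group with match score ≥ 60 (ties
break on KO id) and sums member-gene abundances.

## MGS clustering

Stage 1: average-linkage hierarchical clustering of gene profiles on
distance 1 − Spearman ρ, tree cut at fixed height 1 − 0.9; clusters
with fewer than 25 genes are abandoned. Stage 2: the same procedure on
cluster mean-abundance profiles cut at 1 − 0.8; clusters falling in one
stage-2 group are merged to the union of their genes (the metadata
records how many stage-1 clusters merged). Average linkage is the
conventional choice for correlation-distance gene clustering and is
stable on block structure; the tree is cut at a height, not a cluster
count, and merge ties resolve by cluster id so output is deterministic.
Zero-variance genes are excluded before correlation (Spearman is
undefined there) with a logged warning.

## CAG clustering

Genes detected in more than ten samples (strict) enter canopy
clustering. Seeds are visited in descending mean abundance (gene id as
tiebreak) — deterministic, and well-measured genes make better canopy
centres. A canopy collects every gene with Pearson > 0.9 (T2) against
the seed profile; genes additionally passing Pearson > 0.95 AND
Spearman > 0.7 (T1) leave the seed pool but remain eligible for
membership in later canopies. Centroids are recomputed once as the
member mean (the underlying canopy method is single-pass); single-gene
canopies are discarded. Canopy groups then form greedily in descending
centroid mean abundance: a canopy joins the first group where its
centroid has Pearson > 0.9 with more than 70% of the group's canopies
(strict). Groups may share genes; each shared gene is assigned to the
cluster minimizing 1 − Pearson between the gene and the cluster mean
computed without that gene (leave-one-out, avoiding self-correlation
bias); exact ties go to the larger cluster, then the lower id. Final
clusters are disjoint and size-classed: ≥ 700 genes big CAG, 100–699
small CAG, smaller clusters retained unlabeled. Cluster abundance for
marker testing is the mean of member-gene profiles (sum is available).

## Consensus taxonomy

Valid matches require identity > 0.95 and coverage > 0.9 (strict). At
each rank (strain, species, genus, order) a cluster takes a label only
when more than 90% of **all** its genes — not only genes with matches —
unambiguously support one taxon; a gene with valid matches to two or
more taxa at a rank counts as unannotated there. The strict denominator
matches the empirically high "unknown" rates for gut gene clusters. The
most specific annotated rank is reported alongside the full per-rank
table.

## Biomarker classifier

mRMR uses the MID (difference) criterion with mutual information on
3-bin equal-frequency discretized abundances; MI is computed from the
joint contingency table in nats, with incremental redundancy sums so
ranking hundreds of features stays fast. One global ranking is
computed and prefix subsets of sizes n, n − step, … ≥ 1 are evaluated
(step 5 for genome/gene markers, 1 for cluster markers). Each subset is
scored by leave-one-out cross-validated LDA (plain SVD solver; only
degenerate within-class covariance triggers a logged shrinkage
fallback — always-on shrinkage was found to inflate LOO-MCC for large
noisy subsets and bias the search toward diluted panels) and the MCC of
the pooled confusion matrix, with MCC = 0 when any margin is empty. The
maximal-MCC subset wins, ties to the smaller panel. The final model is
a linear SVM with default regularization on features standardized with
discovery-cohort statistics (relative abundances are O(1e-6); an
unscaled margin objective would ignore them); ROC points come from the
decision scores and AUC from the trapezoid rule. Validation samples are
never seen by ranking, subset search, scaling, or fitting.

## Synthetic cohorts

The generator emulates: log-normal species abundance (cluster base
signal: per-sample log-normal, σ = 1 by default), gene-level
multiplicative log-normal noise (dispersion σ = 0.3), genes of one
planted cluster sharing the cluster base so within-cluster Spearman is
high and across-cluster near zero, planted case/control fold changes
applied to the cluster base (all genes of an effect cluster shift
together), random dropout zeros (2%) to exercise tie handling, and two
cohorts — discovery 73 + 83, validation 24 + 31 — drawn with one shared
set of gene-level parameters (cluster means, per-gene scales) and
independent sample draws. Background (unclustered) genes carry extra
mass (log-mean offset 3), keeping each planted cluster a few percent of
community mass; without this the relative-abundance closure induces
spurious negative across-cluster correlation. Read simulation draws
pairs from genomes ∝ composition × length; pairs inside shared genomic
regions are emitted as multi-mapping hits to both genomes with the true
origin recorded.

What the generator does **not** emulate: sequencing error and quality,
host contamination, compositional zeros from detection limits (dropout
is i.i.d.), strain-level mosaicism, batch effects, or realistic gene
catalog scale. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure under the stated
noise model, not performance on real stool metagenomes.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: cohorts of
~2,000–2,600 genes and 80–211 samples, 10⁵ read pairs for the
simulation-consistency check, 50 replicates for the null-FDR check, and
a reduced two-run pipeline for the determinism check. Power analysis
fixed one fixture: at 40 vs 40 samples and FDR 5e-4, a 2× fold change
on a cluster is detectable only when between-subject log-SD ≲ 0.75
(rank-sum z ≥ 3.7), so the marker-power fixture uses log-SD 0.5 while
the generator default stays 1.0. Tolerances: relative-abundance columns
sum to 1 within 1e-9; hand-checked abundance arithmetic is exact to
1e-12; cluster-recovery checks require adjusted Rand index ≥ 0.95.

## Known limitations

Canopy clustering is O(seeds × genes) on dense profiles and is not
engineered for million-gene catalogs; the exact rank-sum enumeration is
combinatorial and intentionally capped at group size 10; the q-value
spline can be unstable below a few hundred p-values (BH fallback
recommended there); consensus taxonomy trusts the match table's lineage
strings and does not reconcile conflicting lineages across ranks.
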