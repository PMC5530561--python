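# quantmeta

A quantitative shotgun-metagenomics pipeline for case/control gut
microbiome studies, built around the analysis chain used in
ankylosing-spondylitis (AS) dysbiosis work: abundance profiling with
explicit handling of multi-mapping reads, rarefied gene richness and
alpha diversity, Wilcoxon/q-value differential abundance, co-abundance
clustering into metagenomic species (MGS) and co-abundance gene groups
(CAGs), consensus taxonomy, and an MCC-optimized biomarker classifier
validated on a held-out cohort. Every stage runs end-to-end on
synthetic cohorts with planted ground truth, so the whole pipeline is
testable without any sequence downloads.

## The model

**Read-partition abundance.** Reads paired-mapped to reference genomes
are split per sample into a unique set U (one genome) and a multiple
set M (several genomes). With l the genome length,

```
Ab(S) = Ab(U) + Ab(M)
Ab(U) = Σ_{i∈U} 1/l
Ab(M) = Σ_{i∈M} Co/l ,   Co_s = Ab(U)_s / Σ_j Ab(U)_j
```

so each multi-mapping read is divided among its candidate genomes in
proportion to their unique-read abundance. Gene abundance uses the same
partition over gene lengths, with a relaxation for genes shorter than
the insert: a pair also counts when one end maps inside the gene and
the mate's implied position under an 800 bp insert falls outside it.

**Differential features.** Features below a median-abundance floor in
both groups are discarded (genes 1e-7, clusters 1e-8); the remainder
get a two-sided Wilcoxon rank-sum test (exact enumeration for small
groups, tie-corrected normal approximation otherwise) and Storey
q-values with a spline-smoothed π₀. Stage thresholds: genes q < 0.001,
KEGG orthology groups q < 0.005, cluster markers q < 0.0005.

**MGS.** Differentially abundant genes are clustered by average-linkage
hierarchical clustering on 1 − Spearman ρ cut at ρ = 0.9; clusters with
fewer than 25 genes are dropped; a second pass on cluster mean profiles
at ρ = 0.8 merges co-varying clusters.

**CAGs.** Genes detected in more than ten samples enter single-pass
canopy clustering (membership T2: Pearson > 0.9 against the seed;
seed-pool removal T1: Pearson > 0.95 and Spearman > 0.7; singleton
canopies discarded), canopies merge into groups when correlated with
more than 70% of a group's canopies, shared genes resolve to their
closest cluster, and clusters are size-classed: ≥ 700 genes "big CAG",
100–699 "small CAG".

**Taxonomy.** Gene matches with identity > 0.95 and coverage > 0.9 are
valid; a cluster is annotated at a rank when more than 90% of its genes
unambiguously match one taxon.

**Classifier.** Candidate markers are ranked by mRMR; prefix subsets
(step 5, or 1 for cluster markers) are scored by leave-one-out LDA and
the Matthews correlation coefficient; the best subset trains a linear
SVM whose ROC/AUC are reported on the discovery and an independent
validation cohort.

## Worked example

The numbered drivers under `analysis/` run one synthetic study (73 + 83
discovery samples, 24 + 31 validation, five planted clusters, two with
case/control fold changes) stage by stage into `results/run/`:

```
$ python analysis/01_simulate_cohorts.py
discovery cohort: 1810 genes x 156 samples (73 cases, 83 controls)
hit table: 20000 read pairs, 1579 multi-mapping

$ python analysis/02_abundance_profiling.py
6 genomes; Pearson(estimate, truth) = 1.0000

$ python analysis/04_differential_genes.py
921 / 1810 genes significant at q < 0.001 (pi0 = 0.397)
planted effect genes recovered: 920 / 920

$ python analysis/05_cluster_mgs_cag.py
mgs_membership.tsv: 2 clusters {'MGS': 2}, ARI vs planted truth = 1.000
```

The multi-mapping reads came from shared genomic regions, yet the
partition estimator still matches the recorded per-read truth; the
differential stage recovers all 920 planted effect genes (plus one
false positive at q < 0.001), and the MGS stage groups them exactly
into the two planted effect clusters. The same stages are available as
a CLI (`quantmeta simulate|abundance|diversity|difftest|mgs|cag|
annotate|classify|run`) and as one orchestrated run
(`quantmeta run --config cfg.yaml --out-dir DIR`) that writes a
manifest with parameter and output hashes; re-running a config
reproduces byte-identical outputs.

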