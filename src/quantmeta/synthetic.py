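"""Synthetic references, hit tables, and case/control cohorts.

Everything the pipeline consumes can be generated here with known
ground truth: toy reference genomes with shared (multi-mapping) regions,
read-pair hit tables with recorded true origins, and two-cohort
gene-abundance matrices with planted co-abundance clusters and planted
case/control fold changes.

The cohort generator mirrors the study design it emulates: a discovery
cohort of 73 cases and 83 controls and an independent validation cohort
of 24 cases and 31 controls.  Genes of one planted cluster share a
common per-sample log-normal base signal times i.i.d. multiplicative
log-normal gene noise, so within-cluster Spearman correlation is high
and across-cluster correlation is ~0; disease effects multiply the
cluster base signal for case samples so all genes of a planted cluster
shift together.  Columns are renormalized to relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import HIT_COLUMNS

READ_LENGTH = 100
PAIR_INSERT = 300  # genomic span of a simulated read pair


@dataclass
class SharedRegion:
    genome_a: str
    genome_b: str
    start_a: int
    start_b: int
    length: int


@dataclass
class SyntheticReferences:
    genomes: list  # (genome id, length bp, taxon label)
    shared_regions: list[SharedRegion]
    genes: list  # (gene id, genome id, start, end) 0-based half-open

    @property
    def lengths(self) -> pd.Series:
        return pd.Series({g: l for g, l, _ in self.genomes}, dtype=float)

    @property
    def gene_lengths(self) -> pd.Series:
        return pd.Series({g: e - s for g, _, s, e in self.genes}, dtype=float)


def generate_references(n_genomes: int, length_range=(10_000, 20_000),
                        shared_fraction: float = 0.0, seed: int = 0) -> SyntheticReferences:
    """Toy genomes with tiled genes and pairwise shared regions.

    Genomes are randomly paired (disjoint pairs); each pair gets one
    shared region of ``shared_fraction * min(pair lengths)`` bp placed
    at a random offset in both genomes.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not 0 <= shared_fraction < 1:
        raise ValueError("shared_fraction must lie in [0, 1)")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid length_range")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genomes)
    genomes = [(f"genome_{i}", int(lengths[i]), f"taxon_{i}") for i in range(n_genomes)]

    genes = []
    for gid, length, _ in genomes:
        pos, k = 0, 0
        while True:
            gene_len = int(rng.integers(300, 1501))
            if pos + gene_len > length:
                break
            genes.append((f"{gid}:gene_{k}", gid, pos, pos + gene_len))
            pos += gene_len + int(rng.integers(50, 201))
            k += 1

    shared = []
    if shared_fraction > 0 and n_genomes >= 2:
        order = rng.permutation(n_genomes)
        for i in range(0, n_genomes - 1, 2):
            a, b = int(order[i]), int(order[i + 1])
            sr_len = int(round(shared_fraction * min(lengths[a], lengths[b])))
            if sr_len == 0:
                continue
            start_a = int(rng.integers(0, lengths[a] - sr_len + 1))
            start_b = int(rng.integers(0, lengths[b] - sr_len + 1))
            shared.append(SharedRegion(genomes[a][0], genomes[b][0],
                                       start_a, start_b, sr_len))
    return SyntheticReferences(genomes, shared, genes)


def _pair_records(read_id, genome, start, paired_flag=1):
    """Two genome hit records (both ends) for one read pair."""
    e1 = (read_id, 1, genome, "genome", start, start + READ_LENGTH, paired_flag)
    e2 = (read_id, 2, genome, "genome",
          start + PAIR_INSERT - READ_LENGTH, start + PAIR_INSERT, paired_flag)
    return [e1, e2]


def simulate_hit_table(references: SyntheticReferences, composition,
                       n_read_pairs: int, seed: int = 0,
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Draw read pairs and emit genome + gene hit records.

    Each pair comes from a genome with probability proportional to
    composition x genome length; a pair lying entirely inside a shared
    region is emitted as multi-mapping (paired hits to both genomes),
    others as unique.  Gene records are emitted for every read end fully
    inside a gene of the true origin genome, with coordinates relative
    to the gene start.  Returns (hit table, true origin per read pair).
    """
    composition = np.asarray(composition, float)
    if len(composition) != len(references.genomes):
        raise ValueError("composition length must match the number of genomes")
    if (composition < 0).any() or not np.isclose(composition.sum(), 1.0, atol=1e-6):
        raise ValueError("composition must be a probability vector over genomes")

    lengths = np.array([l for _, l, _ in references.genomes], float)
    weights = composition * lengths
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    origins = rng.choice(len(references.genomes), size=n_read_pairs, p=weights)

    genome_ids = [g for g, _, _ in references.genomes]
    shared_by_genome: dict[str, list[tuple[SharedRegion, bool]]] = {}
    for sr in references.shared_regions:
        shared_by_genome.setdefault(sr.genome_a, []).append((sr, True))
        shared_by_genome.setdefault(sr.genome_b, []).append((sr, False))
    genes_by_genome: dict[str, list] = {}
    for gene in references.genes:
        genes_by_genome.setdefault(gene[1], []).append(gene)

    records, truth = [], {}
    for i, gi in enumerate(origins):
        gid = genome_ids[gi]
        read_id = f"read_{i}"
        truth[read_id] = gid
        start = int(rng.integers(0, int(lengths[gi]) - PAIR_INSERT + 1))
        end = start + PAIR_INSERT

        records.extend(_pair_records(read_id, gid, start))
        for sr, is_a in shared_by_genome.get(gid, []):
            s0 = sr.start_a if is_a else sr.start_b
            if start >= s0 and end <= s0 + sr.length:
                mate_gid = sr.genome_b if is_a else sr.genome_a
                mate_start = (sr.start_b if is_a else sr.start_a) + (start - s0)
                records.extend(_pair_records(read_id, mate_gid, mate_start))

        for gene_id, _, gs, ge in genes_by_genome.get(gid, []):
            spans = [(start, start + READ_LENGTH, 1),
                     (end - READ_LENGTH, end, 2)]
            inside = [(a, b, e) for a, b, e in spans if a >= gs and b <= ge]
            for a, b, e in inside:
                records.append((read_id, e, gene_id, "gene",
                                a - gs, b - gs, 1 if len(inside) == 2 else 0))

    hits = pd.DataFrame(records, columns=HIT_COLUMNS)
    return hits, pd.Series(truth, name="true_origin")


@dataclass
class CohortSpec:
    """Conditions for one synthetic case/control cohort."""

    n_cases: int = 73
    n_controls: int = 83
    cluster_sizes: tuple = (800, 300, 120, 60, 30)
    n_noise_genes: int = 500
    effects: dict = field(default_factory=lambda: {0: 3.0, 2: 1 / 3})
    base_log_mean: float = np.log(1e-6)
    base_log_sd: float = 1.0
    # noise genes carry extra mass so planted clusters stay a small
    # fraction of the community, as a real species does; this keeps the
    # relative-abundance closure from inducing across-cluster correlation
    background_log_mean_offset: float = 3.0
    dispersion: float = 0.3  # sd of per-gene per-sample log-normal noise
    gene_scale_sd: float = 0.5  # static per-gene lognormal scale spread
    dropout: float = 0.02
    seed: int = 0


@dataclass
class CohortTruth:
    n_cases: int
    n_controls: int
    cluster_membership: dict  # gene id -> planted cluster id
    effect_features: dict  # feature id -> fold change
    base_abundance: dict  # feature id -> mean relative abundance
    noise_model: dict
    seed: int


def _check_spec(spec: CohortSpec) -> None:
    if any(s < 1 for s in spec.cluster_sizes):
        raise ValueError("cluster sizes must be >= 1")
    for k in spec.effects:
        if k >= len(spec.cluster_sizes):
            raise ValueError(f"effect cluster {k} does not exist")
    if any(f <= 0 for f in spec.effects.values()):
        raise ValueError("fold changes must be > 0")


def _draw_gene_params(spec: CohortSpec, rng: np.random.Generator) -> dict:
    """Gene-level truth shared by every cohort drawn from one spec:
    cluster log-means, static per-gene scales, noise-gene log-means."""
    return {
        "cluster_mu": spec.base_log_mean + rng.normal(0, 0.5,
                                                      size=len(spec.cluster_sizes)),
        "gene_scale": [np.exp(spec.gene_scale_sd * rng.normal(size=s))
                       for s in spec.cluster_sizes],
        "noise_mu": (spec.base_log_mean + spec.background_log_mean_offset
                     + rng.normal(0, 0.5, size=spec.n_noise_genes)),
    }


def _draw_samples(spec: CohortSpec, params: dict, rng: np.random.Generator,
                  n_cases: int, n_controls: int, prefix: str = "S",
                  ) -> tuple[pd.DataFrame, pd.Series, CohortTruth]:
    n_samples = n_cases + n_controls
    samples = [f"{prefix}{i:03d}" for i in range(n_samples)]
    labels = pd.Series(["case"] * n_cases + ["control"] * n_controls,
                       index=samples, name="group")
    is_case = (labels == "case").to_numpy()

    blocks, gene_ids, membership, effect_features = [], [], {}, {}
    for k, size in enumerate(spec.cluster_sizes):
        cluster_id = f"cluster_{k}"
        base = np.exp(params["cluster_mu"][k]
                      + spec.base_log_sd * rng.normal(size=n_samples))
        fold = spec.effects.get(k, 1.0)
        base = np.where(is_case, base * fold, base)
        noise = np.exp(spec.dispersion * rng.normal(size=(size, n_samples)))
        blocks.append(params["gene_scale"][k][:, None] * base[None, :] * noise)
        ids = [f"{cluster_id}:g{j:04d}" for j in range(size)]
        gene_ids.extend(ids)
        for g in ids:
            membership[g] = cluster_id
            if fold != 1.0:
                effect_features[g] = fold

    if spec.n_noise_genes:
        noise = np.exp(params["noise_mu"][:, None]
                       + spec.base_log_sd * rng.normal(size=(spec.n_noise_genes,
                                                             n_samples)))
        blocks.append(noise)
        gene_ids.extend(f"noise:g{j:04d}" for j in range(spec.n_noise_genes))

    x = np.vstack(blocks)
    if spec.dropout > 0:
        x = np.where(rng.random(x.shape) < spec.dropout, 0.0, x)
    matrix = pd.DataFrame(x, index=gene_ids, columns=samples)
    matrix = matrix / matrix.sum(axis=0)

    truth = CohortTruth(
        n_cases=n_cases,
        n_controls=n_controls,
        cluster_membership=membership,
        effect_features=effect_features,
        base_abundance=matrix.mean(axis=1).to_dict(),
        noise_model={"distribution": "log-normal multiplicative",
                     "dispersion": spec.dispersion},
        seed=spec.seed,
    )
    return matrix, labels, truth


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series, CohortTruth]:
    """Gene x sample relative-abundance matrix with planted structure."""
    _check_spec(spec)
    seq = np.random.SeedSequence(spec.seed)
    param_rng, sample_rng = (np.random.default_rng(s) for s in seq.spawn(2))
    params = _draw_gene_params(spec, param_rng)
    return _draw_samples(spec, params, sample_rng, spec.n_cases, spec.n_controls)


def generate_paired_cohorts(spec: CohortSpec, seed: int | None = None,
                            validation_cases: int = 24,
                            validation_controls: int = 31):
    """Discovery + validation cohorts sharing one gene-level truth but
    with independent sample draws."""
    _check_spec(spec)
    base_seed = spec.seed if seed is None else seed
    seq = np.random.SeedSequence(base_seed)
    param_rng, disc_rng, val_rng = (np.random.default_rng(s) for s in seq.spawn(3))
    params = _draw_gene_params(spec, param_rng)
    discovery = _draw_samples(spec, params, disc_rng,
                              spec.n_cases, spec.n_controls, prefix="D")
    validation = _draw_samples(spec, params, val_rng,
                               validation_cases, validation_controls, prefix="V")
    return discovery, validation


def generate_match_table(truth: CohortTruth, annotated_fraction: float = 0.95,
                         seed: int = 0) -> pd.DataFrame:
    """Gene -> reference match table consistent with the planted clusters.

    Genes of planted cluster k match taxon lineage k at high identity
    and coverage; a fraction of genes carries no match (emulating
    catalog genes without close reference genomes).  Noise genes go
    unmatched.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, cluster in truth.cluster_membership.items():
        if rng.random() > annotated_fraction:
            continue
        k = cluster.split("_")[-1]
        rows.append({
            "gene": gene,
            "strain": f"strain_{k}",
            "species": f"species_{k}",
            "genus": f"genus_{k}",
            "order": f"order_{k}",
            "identity": float(rng.uniform(0.96, 1.0)),
            "coverage": float(rng.uniform(0.92, 1.0)),
        })
    return pd.DataFrame(rows, columns=["gene", "strain", "species", "genus",
                                       "order", "identity", "coverage"])


def generate_ko_table(gene_ids, n_kos: int = 50, assigned_fraction: float = 0.4,
                      seed: int = 0) -> pd.DataFrame:
    """Gene -> KO score table; ~assigned_fraction of genes get a
    qualifying (score >= 60) best match."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in gene_ids:
        if rng.random() > assigned_fraction:
            continue
        ko = f"K{int(rng.integers(0, n_kos)):05d}"
        rows.append({"gene": gene, "ko": ko, "score": float(rng.uniform(60, 300))})
        if rng.random() < 0.3:  # a weaker secondary match
            ko2 = f"K{int(rng.integers(0, n_kos)):05d}"
            rows.append({"gene": gene, "ko": ko2, "score": float(rng.uniform(20, 59))})
    return pd.DataFrame(rows, columns=["gene", "ko", "score"])
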