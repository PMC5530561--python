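"""Abundance profiling from read-to-target hit tables.

Species (reference-genome) abundance uses only paired-match reads and
splits each sample's reads into a unique set U (reads hitting a single
genome) and a multiple set M (reads hitting several genomes).  With l the
target length in bp::

    Ab(S) = Ab(U) + Ab(M)
    Ab(U) = sum_{i in U} 1 / l
    Ab(M) = sum_{i in M} Co_s / l_s
    Co_s  = Ab(U)_s / sum_j Ab(U)_j        (j over the genomes read i hits)

so each multi-mapping read is divided among its candidate targets in
proportion to their unique-read abundance, computed once from the global
unique counts (no iterative re-estimation).  Candidates with zero unique
abundance receive weight 0; a read whose candidates all have zero unique
abundance contributes nothing and is tallied in the diagnostics.

Gene abundance applies the same partition over gene lengths but relaxes
read qualification: genes are shorter than genomes, so a pair also counts
when only one end lies inside the gene and the mate's implied position
under a fixed insert size (default 800 bp) falls outside the gene span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIT_COLUMNS = ["read_id", "end", "target_id", "target_kind", "start", "stop", "paired_flag"]

DEFAULT_INSERT_SIZE = 800


@dataclass
class AbundanceDiagnostics:
    """Side counts emitted by the abundance estimators."""

    n_unique_reads: int = 0
    n_multi_reads: int = 0
    n_dropped_reads: int = 0  # multi-reads whose candidates all had Ab(U)=0
    n_skipped_records: int = 0  # records with missing/invalid coordinates
    dropped_reads: list = field(default_factory=list)


def _check_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return hits


def _partition_reads(read_targets: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Split read -> candidate-target-set mapping into unique and multi."""
    n_targets = read_targets.map(len)
    unique = read_targets[n_targets == 1].map(lambda s: next(iter(s)))
    multi = read_targets[n_targets > 1]
    return unique, multi


def _partitioned_abundance(
    read_targets: pd.Series,
    lengths: pd.Series,
    diagnostics: AbundanceDiagnostics,
) -> pd.Series:
    """Ab(S) = Ab(U) + Ab(M) over an arbitrary read -> targets mapping."""
    lengths = lengths.astype(float)
    if (lengths <= 0).any():
        raise ValueError("target lengths must be positive")

    unique, multi = _partition_reads(read_targets)
    diagnostics.n_unique_reads = len(unique)
    diagnostics.n_multi_reads = len(multi)

    unique_counts = unique.value_counts().reindex(lengths.index, fill_value=0)
    ab_u = unique_counts / lengths

    ab_m = pd.Series(0.0, index=lengths.index)
    if len(multi):
        # identical candidate sets share one Co computation
        for targets, reads in multi.groupby(multi.map(frozenset)):
            targets = sorted(targets)
            u = ab_u.reindex(targets, fill_value=0.0)
            total = u.sum()
            if total == 0:
                diagnostics.n_dropped_reads += len(reads)
                diagnostics.dropped_reads.extend(reads.index.tolist())
                continue
            co = u / total
            ab_m.loc[targets] += len(reads) * co / lengths.loc[targets]

    ab = ab_u + ab_m
    ab.name = "abundance"
    return ab


def species_abundance(
    hits: pd.DataFrame,
    lengths: pd.Series | dict,
    return_diagnostics: bool = False,
) -> pd.Series | tuple[pd.Series, AbundanceDiagnostics]:
    """Reference-genome abundance (reads/bp) from paired-match hits.

    Parameters
    ----------
    hits
        Hit table with columns ``read_id, end, target_id, target_kind,
        start, stop, paired_flag``.  Only records with
        ``target_kind == "genome"`` and ``paired_flag == 1`` enter the
        species computation.
    lengths
        Genome id -> length in bp.
    """
    hits = _check_hits(hits)
    lengths = pd.Series(lengths, dtype=float)
    h = hits[(hits["target_kind"] == "genome") & (hits["paired_flag"] == 1)]
    unknown = set(h["target_id"]) - set(lengths.index)
    if unknown:
        raise ValueError(f"hits reference targets with no length: {sorted(unknown)[:5]}")

    diagnostics = AbundanceDiagnostics()
    read_targets = h.groupby("read_id")["target_id"].agg(set)
    ab = _partitioned_abundance(read_targets, lengths, diagnostics)
    if return_diagnostics:
        return ab, diagnostics
    return ab


def _qualifying_gene_pairs(
    hits: pd.DataFrame,
    gene_lengths: pd.Series,
    insert_size: int,
    diagnostics: AbundanceDiagnostics,
) -> pd.Series:
    """read -> set of genes the pair qualifies for under the boundary rule.

    A pair qualifies for a gene when both ends map within it, or when one
    end maps within it and the mate's implied position under the insert
    size lies outside the gene span (past either boundary).
    """
    h = hits[hits["target_kind"] == "gene"]
    bad = h["start"].isna() | h["stop"].isna()
    diagnostics.n_skipped_records = int(bad.sum())
    h = h[~bad]

    qualified: dict = {}
    for (read_id, gene), grp in h.groupby(["read_id", "target_id"], sort=False):
        length = gene_lengths.loc[gene]
        ends = set(grp["end"])
        ok = False
        if len(ends) >= 2:
            ok = True  # both ends inside the gene
        else:
            rec = grp.iloc[0]
            mate_beyond_end = rec["start"] + insert_size > length
            mate_before_start = rec["stop"] - insert_size < 0
            ok = bool(mate_beyond_end or mate_before_start)
        if ok:
            qualified.setdefault(read_id, set()).add(gene)
    return pd.Series(qualified, dtype=object)


def gene_abundance(
    hits: pd.DataFrame,
    gene_lengths: pd.Series | dict,
    insert_size: int = DEFAULT_INSERT_SIZE,
    return_diagnostics: bool = False,
) -> pd.Series | tuple[pd.Series, AbundanceDiagnostics]:
    """Gene abundance (reads/bp) with the single-end boundary relaxation."""
    hits = _check_hits(hits)
    gene_lengths = pd.Series(gene_lengths, dtype=float)
    diagnostics = AbundanceDiagnostics()
    read_genes = _qualifying_gene_pairs(hits, gene_lengths, insert_size, diagnostics)
    if read_genes.empty:
        ab = pd.Series(0.0, index=gene_lengths.index, name="abundance")
        if return_diagnostics:
            return ab, diagnostics
        return ab
    ab = _partitioned_abundance(read_genes, gene_lengths, diagnostics)
    if return_diagnostics:
        return ab, diagnostics
    return ab


def normalize_relative(v: pd.Series) -> pd.Series:
    """Scale a non-negative abundance vector to relative abundance (sum 1)."""
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    total = float(v.sum())
    if total == 0:
        raise ValueError("cannot normalize an all-zero abundance vector")
    out = v / total
    out.attrs["normalized"] = True
    return out


def normalize_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Column-wise relative-abundance normalization of a feature x sample matrix."""
    sums = m.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("matrix has all-zero sample columns")
    return m / sums
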