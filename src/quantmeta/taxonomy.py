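"""Consensus taxonomic annotation of gene clusters from match tables.

A gene's alignment against reference genomes is a valid match when
identity > 0.95 and coverage > 0.9 (strict inequalities).  A cluster is
annotated at a rank when more than 90% of ALL its genes (the strict
denominator, matching the high observed "unknown" rates) carry valid
matches to one single taxon at that rank; a gene with valid matches to
two or more distinct taxa at a rank counts as unannotated there.  Ranks
are evaluated from strain up to order and the most specific annotated
rank is reported.
"""

from __future__ import annotations

import pandas as pd

from .clusters import GeneCluster

MIN_IDENTITY = 0.95
MIN_COVERAGE = 0.9
CONSENSUS_FRACTION = 0.9

RANKS = ("strain", "species", "genus", "order")  # most to least specific


def filter_valid_matches(mt: pd.DataFrame, min_identity: float = MIN_IDENTITY,
                         min_coverage: float = MIN_COVERAGE) -> pd.DataFrame:
    """Keep rows with identity > min_identity and coverage > min_coverage."""
    return mt[(mt["identity"] > min_identity) & (mt["coverage"] > min_coverage)]


def annotate_cluster(cluster: GeneCluster, mt: pd.DataFrame,
                     consensus: float = CONSENSUS_FRACTION) -> dict:
    """Per-rank consensus annotation of one cluster.

    ``mt`` must already be restricted to valid matches and carry columns
    ``gene`` plus one column per rank in RANKS.  Returns
    ``{rank: label-or-"unknown", ..., "best_rank": rank-or-None,
    "best_label": label-or-"unknown"}``.
    """
    n = cluster.size
    sub = mt[mt["gene"].isin(cluster.genes)]
    out: dict = {}
    best_rank, best_label = None, "unknown"
    for rank in RANKS:
        label = "unknown"
        if n and not sub.empty:
            taxa_per_gene = sub.groupby("gene")[rank].agg(lambda s: set(s.dropna()))
            votes = taxa_per_gene[taxa_per_gene.map(len) == 1].map(lambda s: next(iter(s)))
            if not votes.empty:
                counts = votes.value_counts()
                if counts.iloc[0] > consensus * n:
                    label = counts.index[0]
        out[rank] = label
        if label != "unknown" and best_rank is None:
            best_rank, best_label = rank, label
    out["best_rank"] = best_rank
    out["best_label"] = best_label
    return out


def annotate_clusters(clusters: list[GeneCluster], mt: pd.DataFrame,
                      consensus: float = CONSENSUS_FRACTION,
                      prefiltered: bool = False) -> pd.DataFrame:
    """Annotation table over a list of clusters (one row per cluster)."""
    if not prefiltered:
        mt = filter_valid_matches(mt)
    rows = []
    for c in clusters:
        ann = annotate_cluster(c, mt, consensus=consensus)
        ann["cluster"] = c.cluster_id
        ann["size"] = c.size
        rows.append(ann)
    cols = ["cluster", "size", *RANKS, "best_rank", "best_label"]
    return pd.DataFrame(rows, columns=cols).set_index("cluster")
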