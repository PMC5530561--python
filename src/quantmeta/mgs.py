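"""Metagenomic species (MGS): two-stage hierarchical co-abundance clustering.

Differentially abundant genes whose abundance profiles co-vary across
individuals are presumed to come from one microbial species.  Stage 1
clusters gene profiles by average-linkage hierarchical clustering with
distance 1 - Spearman rho, cutting the tree at correlation 0.9, and
drops clusters of fewer than 25 genes.  Stage 2 repeats the procedure on
the cluster mean-abundance profiles at correlation 0.8, merging clusters
whose means co-vary (merge-to-union).  The surviving clusters are MGSs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .clusters import MGS_MIN_SIZE, GeneCluster, cluster_profile

STAGE1_THRESHOLD = 0.9
STAGE2_THRESHOLD = 0.8


def _spearman_distance(profiles: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Spearman distance over the rows of ``profiles``."""
    rho = stats.spearmanr(profiles.to_numpy(float), axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    return squareform(d, checks=False)


def _cut(profiles: pd.DataFrame, threshold: float) -> pd.Series:
    """Average-linkage tree cut at distance 1 - threshold; row -> cluster label."""
    if len(profiles) == 1:
        return pd.Series([1], index=profiles.index)
    condensed = _spearman_distance(profiles)
    link = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(link, t=1.0 - threshold + 1e-12, criterion="distance")
    return pd.Series(labels, index=profiles.index)


def identify_mgs(profiles: pd.DataFrame,
                 stage1_threshold: float = STAGE1_THRESHOLD,
                 min_size: int = MGS_MIN_SIZE,
                 stage2_threshold: float = STAGE2_THRESHOLD) -> list[GeneCluster]:
    """Cluster gene abundance profiles (genes x samples) into MGSs.

    Zero-variance genes are excluded before correlation (Spearman is
    undefined for them).  Returns clusters sorted by size (desc), ids
    ``MGS_1, MGS_2, ...``; metadata records the stage-2 merge.
    """
    variances = profiles.var(axis=1)
    dropped = profiles.index[variances == 0]
    if len(dropped):
        warnings.warn(f"excluded {len(dropped)} zero-variance genes", stacklevel=2)
    profiles = profiles.loc[variances > 0]
    if len(profiles) < max(min_size, 2):
        warnings.warn("too few genes for MGS identification", stacklevel=2)
        return []

    stage1 = _cut(profiles, stage1_threshold)
    kept = [members.index.tolist() for _, members in stage1.groupby(stage1)
            if len(members) >= min_size]
    if not kept:
        return []
    kept.sort(key=lambda genes: (-len(genes), genes[0]))

    merged_from = {i: [i] for i in range(len(kept))}
    if len(kept) > 1:
        means = pd.DataFrame(
            {i: cluster_profile(genes, profiles) for i, genes in enumerate(kept)}
        ).T
        stage2 = _cut(means, stage2_threshold)
        merged_from = {}
        for label, members in stage2.groupby(stage2):
            root = min(members.index)
            merged_from[root] = sorted(members.index)

    clusters = []
    for root in sorted(merged_from):
        genes = sorted(g for i in merged_from[root] for g in kept[i])
        clusters.append(GeneCluster(
            cluster_id="",
            genes=genes,
            mean_profile=cluster_profile(genes, profiles),
            kind="MGS",
            metadata={"stage1_clusters_merged": len(merged_from[root])},
        ))
    clusters.sort(key=lambda c: (-c.size, c.genes[0]))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"MGS_{i}"
    return clusters


def top_gene_mean(cluster: GeneCluster, profiles: pd.DataFrame, n: int = 25) -> pd.Series:
    """Mean profile of the cluster's n highest-mean-abundance genes
    (the per-MGS marker-gene summary statistic)."""
    means = profiles.loc[cluster.genes].mean(axis=1)
    top = means.nlargest(n).index
    return profiles.loc[top].mean(axis=0)
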