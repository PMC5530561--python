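"""Co-abundance gene groups (CAGs) by canopy clustering on the full catalog.

Single-pass canopy clustering with a loose membership threshold T2
(Pearson > 0.9 against the seed profile) and a tight threshold T1
(Pearson > 0.95 AND Spearman > 0.7) that removes genes from the seed
pool.  Singleton canopies are discarded.  Canopies are then merged into
groups: walking canopies in descending mean abundance, a canopy joins a
group when its centroid has Pearson > 0.9 with more than 70% of the
group's canopies.  Groups may share genes; each shared gene is resolved
to the cluster whose mean profile (excluding the gene itself) it
correlates with best.  Final clusters are size-classed: >= 700 genes
"big CAG", 100-699 "small CAG".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import (BIG_CAG_MIN_SIZE, SMALL_CAG_MIN_SIZE, GeneCluster,
                       cluster_matrix, cluster_profile)
from .differential import CAG_FDR, CAG_MEDIAN_FLOOR, differential_test

T1_PEARSON = 0.95
T1_SPEARMAN = 0.7
T2_PEARSON = 0.9
GROUP_CORR = 0.9
GROUP_FRACTION = 0.7
MIN_DETECTED_SAMPLES = 10


@dataclass
class Canopy:
    canopy_id: int
    seed_gene: str
    members: list
    centroid: pd.Series


def prefilter_genes(profiles: pd.DataFrame,
                    min_samples: int = MIN_DETECTED_SAMPLES) -> pd.DataFrame:
    """Keep genes detected (abundance > 0) in more than ``min_samples`` samples."""
    detected = (profiles > 0).sum(axis=1)
    return profiles.loc[detected > min_samples]


def _standardize(x: np.ndarray) -> np.ndarray:
    """Rows centred and scaled so that row dot products / n = Pearson r."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # zero-variance rows correlate with nothing
    return (x - mu) / sd


def _seed_order(profiles: pd.DataFrame) -> list:
    """Descending mean abundance, gene id as deterministic tiebreak."""
    means = profiles.mean(axis=1)
    return sorted(profiles.index, key=lambda g: (-means[g], g))


def canopy_cluster(profiles: pd.DataFrame,
                   t1_pearson: float = T1_PEARSON,
                   t1_spearman: float = T1_SPEARMAN,
                   t2_pearson: float = T2_PEARSON,
                   seed_order: list | None = None) -> list[Canopy]:
    """Single-pass canopy clustering over gene profiles (genes x samples).

    Seeds are drawn in ``seed_order`` (default: descending mean
    abundance) from the remaining seed pool; each canopy collects every
    gene with Pearson > T2 against the seed profile, and genes passing
    T1 leave the seed pool.  Centroids are recomputed once as the member
    mean; single-gene canopies are dropped.
    """
    if profiles.empty:
        return []
    order = list(seed_order) if seed_order is not None else _seed_order(profiles)
    genes = profiles.index.to_list()
    x = profiles.to_numpy(float)
    z_pearson = _standardize(x)
    z_spearman = _standardize(stats.rankdata(x, axis=1))
    n = x.shape[1]
    pos = {g: i for i, g in enumerate(genes)}

    in_pool = dict.fromkeys(order, True)
    canopies: list[Canopy] = []
    for seed in order:
        if not in_pool.get(seed, False):
            continue
        in_pool[seed] = False
        i = pos[seed]
        r = z_pearson @ z_pearson[i] / n
        member_idx = np.flatnonzero(r > t2_pearson)
        rho = z_spearman[member_idx] @ z_spearman[i] / n
        tight = (r[member_idx] > t1_pearson) & (rho > t1_spearman)
        for j in member_idx[tight]:
            in_pool[genes[j]] = False
        if len(member_idx) <= 1:
            continue  # canopies containing only one gene are excluded
        members = [genes[j] for j in member_idx]
        centroid = pd.Series(x[member_idx].mean(axis=0), index=profiles.columns)
        canopies.append(Canopy(len(canopies), seed, members, centroid))
    return canopies


def merge_canopies(canopies: list[Canopy],
                   group_corr: float = GROUP_CORR,
                   group_fraction: float = GROUP_FRACTION) -> list[GeneCluster]:
    """Greedy canopy-into-group agglomeration on centroid correlation.

    Canopies are visited in descending centroid mean abundance; one
    joins an existing group when its centroid has Pearson > group_corr
    with more than ``group_fraction`` of the group's canopies, else it
    founds a new group.  Group gene sets are unions and may overlap
    across groups.
    """
    order = sorted(canopies, key=lambda c: (-float(c.centroid.mean()), c.canopy_id))
    groups: list[list[Canopy]] = []
    for canopy in order:
        placed = False
        for group in groups:
            r = np.array([stats.pearsonr(canopy.centroid, m.centroid).statistic
                          for m in group])
            if (r > group_corr).sum() > group_fraction * len(group):
                group.append(canopy)
                placed = True
                break
        if not placed:
            groups.append([canopy])
    clusters = []
    for k, group in enumerate(groups, start=1):
        genes = sorted({g for c in group for g in c.members})
        clusters.append(GeneCluster(
            cluster_id=f"CAG_{k}", genes=genes,
            metadata={"n_canopies": len(group)},
        ))
    return clusters


def resolve_overlaps(groups: list[GeneCluster],
                     profiles: pd.DataFrame) -> list[GeneCluster]:
    """Assign each multiply-clustered gene to its closest cluster.

    Distance = 1 - Pearson between the gene profile and the cluster mean
    profile with the gene itself left out; exact ties go to the larger
    cluster, then the lower cluster id.  Output clusters are disjoint;
    clusters emptied by resolution are dropped and mean profiles are
    recomputed.
    """
    owners: dict[str, list[GeneCluster]] = {}
    for c in groups:
        for g in c.genes:
            owners.setdefault(g, []).append(c)

    assignment: dict[str, str] = {}
    for gene, cands in owners.items():
        if len(cands) == 1:
            assignment[gene] = cands[0].cluster_id
            continue
        best = None
        for c in cands:
            others = [g for g in c.genes if g != gene]
            if not others:
                continue
            mean = profiles.loc[others].mean(axis=0)
            r = stats.pearsonr(profiles.loc[gene], mean).statistic
            d = 1.0 - (0.0 if np.isnan(r) else r)
            key = (round(d, 12), -c.size, c.cluster_id)
            if best is None or key < best[0]:
                best = (key, c.cluster_id)
        assignment[gene] = best[1]

    resolved = []
    for c in groups:
        genes = sorted(g for g in c.genes if assignment[g] == c.cluster_id)
        if not genes:
            continue
        resolved.append(GeneCluster(
            cluster_id=c.cluster_id, genes=genes,
            mean_profile=cluster_profile(genes, profiles),
            metadata=dict(c.metadata),
        ))
    return resolved


def classify_cags(clusters: list[GeneCluster]) -> list[GeneCluster]:
    """Label size classes: >= 700 genes bigCAG, 100-699 smallCAG."""
    for c in clusters:
        if c.size >= BIG_CAG_MIN_SIZE:
            c.kind = "bigCAG"
        elif c.size >= SMALL_CAG_MIN_SIZE:
            c.kind = "smallCAG"
        else:
            c.kind = "unlabeled"
    return clusters


def cag_pipeline(profiles: pd.DataFrame, **kwargs) -> list[GeneCluster]:
    """prefilter -> canopy -> merge -> resolve -> size classes."""
    filtered = prefilter_genes(profiles, kwargs.pop("min_samples", MIN_DETECTED_SAMPLES))
    canopies = canopy_cluster(
        filtered,
        t1_pearson=kwargs.pop("t1_pearson", T1_PEARSON),
        t1_spearman=kwargs.pop("t1_spearman", T1_SPEARMAN),
        t2_pearson=kwargs.pop("t2_pearson", T2_PEARSON),
    )
    groups = merge_canopies(canopies,
                            group_corr=kwargs.pop("group_corr", GROUP_CORR),
                            group_fraction=kwargs.pop("group_fraction", GROUP_FRACTION))
    return classify_cags(resolve_overlaps(groups, filtered))


def cag_marker_test(clusters: list[GeneCluster], profiles: pd.DataFrame,
                    labels: pd.Series, floor: float = CAG_MEDIAN_FLOOR,
                    fdr: float = CAG_FDR, how: str = "mean"):
    """Wilcoxon differential test on cluster abundance profiles.

    Cluster abundance is the mean (or sum) of member gene abundances per
    sample; the median floor applies in both groups before testing.
    """
    m = cluster_matrix(clusters, profiles, how=how)
    return differential_test(m, labels, floor=floor, fdr=fdr)
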