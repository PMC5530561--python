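"""Shared gene-cluster container for MGS and CAG pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# printed size-class bounds
MGS_MIN_SIZE = 25
BIG_CAG_MIN_SIZE = 700
SMALL_CAG_MIN_SIZE = 100


@dataclass
class GeneCluster:
    cluster_id: str
    genes: list
    mean_profile: pd.Series | None = None
    kind: str = "unlabeled"  # MGS | bigCAG | smallCAG | unlabeled
    metadata: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.genes)


def cluster_profile(genes, profiles: pd.DataFrame, how: str = "mean") -> pd.Series:
    """Cluster abundance profile = mean (or sum) of member gene profiles."""
    sub = profiles.loc[list(genes)]
    return sub.mean(axis=0) if how == "mean" else sub.sum(axis=0)


def membership_frame(clusters) -> pd.DataFrame:
    """Long (gene, cluster) table for a list of GeneClusters."""
    rows = [(g, c.cluster_id, c.kind) for c in clusters for g in c.genes]
    return pd.DataFrame(rows, columns=["gene", "cluster", "kind"])


def cluster_matrix(clusters, profiles: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Cluster x sample abundance matrix from member gene profiles."""
    return pd.DataFrame(
        {c.cluster_id: cluster_profile(c.genes, profiles, how) for c in clusters}
    ).T
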