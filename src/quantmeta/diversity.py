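"""Rarefied gene counting and alpha diversity.

Sample read sets are rarefied (uniform subsampling without replacement)
to a common depth, 9 million reads by default, so richness is comparable
across sequencing depths; gene detection after rarefaction is >= 1
assigned read.  Shannon uses the natural log; Simpson is reported in the
Gini-Simpson form 1 - sum p_i^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_RAREFACTION_DEPTH = 9_000_000


@dataclass
class RarefiedSample:
    sample_id: str
    read_ids: np.ndarray
    depth: int
    seed: int
    truncated: bool  # False when depth >= total and all reads were kept


def rarefy(reads, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int = 0,
           sample_id: str = "") -> RarefiedSample:
    """Uniformly subsample read ids without replacement to ``depth``."""
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    reads = np.asarray(reads)
    rng = np.random.default_rng(seed)
    if depth >= len(reads):
        return RarefiedSample(sample_id, reads.copy(), depth, seed, truncated=False)
    drawn = rng.choice(reads, size=depth, replace=False)
    return RarefiedSample(sample_id, drawn, depth, seed, truncated=True)


def count_genes(x) -> int:
    """Number of detected genes.

    Accepts either an abundance vector (detection = abundance > 0) or an
    iterable of per-read gene assignments (detection = >= 1 read).
    """
    if isinstance(x, pd.Series):
        return int((x > 0).sum())
    return len(set(x))


def alpha_diversity(p: pd.Series, index: str = "shannon", atol: float = 1e-6) -> float:
    """Shannon (-sum p ln p) or Gini-Simpson (1 - sum p^2) diversity.

    ``p`` must be a relative abundance vector summing to 1.
    """
    values = np.asarray(p, dtype=float)
    if (values < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if not np.isclose(values.sum(), 1.0, atol=atol):
        raise ValueError(f"input must be normalized (sum={values.sum():.6g})")
    values = values[values > 0]
    if index == "shannon":
        return float(-(values * np.log(values)).sum())
    if index == "simpson":
        return float(1.0 - (values ** 2).sum())
    raise ValueError(f"unknown diversity index: {index!r}")


def diversity_table(abundance: pd.DataFrame, depth: int | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Per-sample gene count, Shannon and Simpson for a feature x sample matrix.

    When ``depth`` is given, each sample's relative abundances are
    converted to a multinomial read draw of that depth first (a
    count-level rarefaction surrogate for matrices that no longer carry
    individual reads).
    """
    rows = []
    rng = np.random.default_rng(seed)
    for sample in abundance.columns:
        v = abundance[sample]
        if depth is not None:
            p = v / v.sum()
            counts = rng.multinomial(depth, p.values)
            v = pd.Series(counts, index=v.index, dtype=float)
        p = v / v.sum()
        rows.append({
            "sample": sample,
            "gene_count": count_genes(v),
            "shannon": alpha_diversity(p, "shannon"),
            "simpson": alpha_diversity(p, "simpson"),
        })
    return pd.DataFrame(rows).set_index("sample")
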