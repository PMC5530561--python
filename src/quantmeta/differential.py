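"""Differential abundance testing: abundance floor, Wilcoxon rank-sum,
Storey q-values with spline pi0, and KO functional aggregation.

Stage presets (floor on the group medians, FDR threshold on q):

* genes:        floor 1e-7, q < 0.001 (methods preset) or mean-abundance
                floor 1e-7 with q < 1e-4 (results preset)
* KO groups:    q < 0.005
* CAG clusters: floor 1e-8, q < 0.0005

A feature is discarded only when its median abundance is below the floor
in BOTH groups.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

# printed defaults, exposed for configs
GENE_MEDIAN_FLOOR = 1e-7
GENE_FDR = 1e-3
GENE_RESULTS_MEAN_FLOOR = 1e-7
GENE_RESULTS_FDR = 1e-4
KO_FDR = 5e-3
CAG_MEDIAN_FLOOR = 1e-8
CAG_FDR = 5e-4
KO_MIN_SCORE = 60

EXACT_GROUP_SIZE_CUTOFF = 10

PRESETS = {
    "methods_preset": {"floor": GENE_MEDIAN_FLOOR, "floor_stat": "median", "fdr": GENE_FDR},
    "results_preset": {"floor": GENE_RESULTS_MEAN_FLOOR, "floor_stat": "mean", "fdr": GENE_RESULTS_FDR},
}


def _split_groups(m: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = pd.Series(labels).reindex(m.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    case, control = ("case", "control") if set(groups) == {"case", "control"} else groups
    return m.loc[:, labels == case], m.loc[:, labels == control]


def filter_low_abundance(m: pd.DataFrame, labels: pd.Series, floor: float,
                         stat: str = "median") -> pd.DataFrame:
    """Drop features whose per-group ``stat`` abundance is below ``floor``
    in both groups."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    ga, gb = _split_groups(m, labels)
    agg = getattr(ga, stat)(axis=1), getattr(gb, stat)(axis=1)
    keep = (agg[0] >= floor) | (agg[1] >= floor)
    out = m.loc[keep]
    if out.empty and not m.empty:
        warnings.warn("abundance floor removed every feature", stacklevel=2)
    return out


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation-exact rank-sum p with mid-rank ties.

    Enumerates all assignments of the pooled observations to the smaller
    group and counts rank sums at least as far from their mean as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    dev = abs(observed - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(m: pd.DataFrame, labels: pd.Series,
                      exact_cutoff: int = EXACT_GROUP_SIZE_CUTOFF) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test.

    Exact enumeration when the smaller group has <= ``exact_cutoff``
    samples, tie-corrected normal approximation with continuity
    correction otherwise.  Features constant across all samples get p=1.
    Returns a frame with group medians, direction, and p.
    """
    ga, gb = _split_groups(m, labels)
    if ga.shape[1] < 2 or gb.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")

    xa, xb = ga.to_numpy(float), gb.to_numpy(float)
    constant = (np.ptp(np.hstack([xa, xb]), axis=1) == 0)

    if min(xa.shape[1], xb.shape[1]) <= exact_cutoff:
        p = np.array([
            1.0 if constant[i] else _exact_rank_sum_p(xa[i], xb[i])
            for i in range(len(m))
        ])
    else:
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided",
                                     method="asymptotic", use_continuity=True)
        p = np.where(constant, 1.0, res.pvalue)
    p = np.clip(p, 0.0, 1.0)

    med_a = np.median(xa, axis=1)
    med_b = np.median(xb, axis=1)
    direction = np.select([med_a > med_b, med_a < med_b],
                          ["case-enriched", "control-enriched"], default="none")
    return pd.DataFrame({
        "median_case": med_a,
        "median_control": med_b,
        "direction": direction,
        "p": p,
    }, index=m.index)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey pi0: spline-smoothed pi0(lambda) evaluated at max lambda."""
    p = np.asarray(p, float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    spline = interpolate.UnivariateSpline(lambdas, pi0_lambda, k=3)
    pi0 = float(spline(lambdas.max()))
    return float(np.clip(pi0, 1e-8, 1.0))


def estimate_qvalues(p, method: str = "storey") -> tuple[np.ndarray, float]:
    """q-values for a vector of p-values.

    ``storey``: pi0 from the lambda-spline estimate (needs >= 10 p-values),
    q_(i) = min over j>=i of pi0 * m * p_(j) / j.  ``bh``:
    Benjamini-Hochberg with pi0 fixed at 1.
    """
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bh" or (method == "storey" and m < 10):
        _, q, _, _ = multipletests(p, method="fdr_bh")
        return q, 1.0
    if method != "storey":
        raise ValueError(f"unknown method: {method!r}")
    pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q, pi0


def differential_test(m: pd.DataFrame, labels: pd.Series, floor: float,
                      fdr: float, floor_stat: str = "median",
                      q_method: str = "storey") -> tuple[pd.DataFrame, float]:
    """Floor filter -> rank-sum -> q-values; flags q < fdr as significant."""
    filtered = filter_low_abundance(m, labels, floor, stat=floor_stat)
    if filtered.empty:
        return filtered.assign(p=[], q=[], significant=[]), 1.0
    res = wilcoxon_rank_sum(filtered, labels)
    q, pi0 = estimate_qvalues(res["p"].to_numpy(), method=q_method)
    res["q"] = q
    res["significant"] = res["q"] < fdr
    return res, pi0


def aggregate_ko(gene_matrix: pd.DataFrame, ko_scores: pd.DataFrame,
                 min_score: float = KO_MIN_SCORE) -> pd.DataFrame:
    """Sum gene abundances into KEGG orthology groups.

    Each gene goes to its highest-scoring KO with score >= ``min_score``
    (score ties broken by KO id); unassignable genes are excluded.
    ``ko_scores`` needs columns gene, ko, score.
    """
    t = ko_scores[ko_scores["score"] >= min_score]
    t = t[t["gene"].isin(gene_matrix.index)]
    if t.empty:
        return pd.DataFrame(index=pd.Index([], name="ko"),
                            columns=gene_matrix.columns, dtype=float)
    t = t.sort_values(["gene", "score", "ko"], ascending=[True, False, True])
    assignment = t.drop_duplicates("gene").set_index("gene")["ko"]
    ko_matrix = gene_matrix.loc[assignment.index].groupby(assignment).sum()
    ko_matrix.index.name = "ko"
    return ko_matrix.sort_index()
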