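"""Biomarker panel selection and case/control classification.

Candidate features (reference-genome, gene, or cluster abundances) are
ranked by mRMR (MID difference form, mutual information on 3-bin
equal-frequency discretized abundances).  Prefix subsets of the ranking
(sizes n, n-step, n-2*step, ... >= 1; step 5 for genome/gene markers,
1 for cluster markers) are scored by leave-one-out cross-validated LDA
and the Matthews correlation coefficient of the pooled confusion matrix:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

(denominator 0 => MCC 0).  The highest-MCC subset (ties -> smallest)
becomes the marker panel; a linear SVM trained on the discovery cohort
provides decision scores for ROC curves and trapezoid AUC on both the
discovery and the held-out validation cohort.  Validation samples never
enter ranking or subset selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MRMR_BINS = 3
SUBSET_STEP = 5
CLUSTER_SUBSET_STEP = 1


@dataclass
class MarkerPanel:
    feature_kind: str
    selected: list
    ranking: list
    mcc_trace: dict  # subset size -> LOO-LDA MCC
    best_mcc: float
    model: object = None
    roc: dict = field(default_factory=dict)  # cohort -> (fpr, tpr, thresholds)
    auc: dict = field(default_factory=dict)  # cohort -> AUC


def _encode_labels(labels: pd.Series) -> np.ndarray:
    groups = sorted(pd.Series(labels).unique())
    if len(groups) != 2:
        raise ValueError(f"expected two classes, got {groups}")
    positive = "case" if "case" in groups else groups[0]
    return (pd.Series(labels) == positive).to_numpy(int)


def _discretize(x: np.ndarray, bins: int = MRMR_BINS) -> np.ndarray:
    """Equal-frequency binning; constant features collapse to one bin."""
    try:
        return np.asarray(pd.qcut(x, bins, labels=False, duplicates="drop"), dtype=int)
    except ValueError:
        return np.zeros(len(x), dtype=int)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats between two integer-coded discrete vectors, from the
    joint contingency table."""
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float((joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])).sum())


def mrmr_rank(features: pd.DataFrame, labels: pd.Series,
              n_select: int | None = None, bins: int = MRMR_BINS) -> list:
    """Greedy max-relevance-min-redundancy (MID) feature ordering.

    ``features`` is feature x sample; relevance and redundancy are
    mutual information on discretized abundances.  Deterministic: ties
    break on feature id.
    """
    if n_select is None:
        n_select = len(features)
    if n_select > len(features):
        raise ValueError("n_select exceeds the number of features")
    y = _encode_labels(pd.Series(labels).reindex(features.columns))
    ids = list(features.index)
    disc = {f: _discretize(features.loc[f].to_numpy(float), bins) for f in ids}
    relevance = {f: mutual_information(disc[f], y) for f in ids}

    selected: list = []
    remaining = sorted(ids, key=lambda f: (-relevance[f], f))
    redundancy_sum = dict.fromkeys(ids, 0.0)  # sum of MI(f, s) over selected s
    while remaining and len(selected) < n_select:
        if not selected:
            best = remaining[0]
        else:
            k = len(selected)
            best = min(remaining,
                       key=lambda f: (-(relevance[f] - redundancy_sum[f] / k), f))
        selected.append(best)
        remaining.remove(best)
        for f in remaining:
            redundancy_sum[f] += mutual_information(disc[f], disc[best])
    return selected


def matthews_cc(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC from a 2x2 confusion matrix; 0 when any margin is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def loo_lda_mcc(features: pd.DataFrame, labels: pd.Series) -> float:
    """Leave-one-out cross-validated LDA, scored by pooled-confusion MCC."""
    y = _encode_labels(pd.Series(labels).reindex(features.columns))
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("both classes need >= 2 samples")
    x = features.to_numpy(float).T  # samples x features
    n = len(y)
    pred = np.empty(n, dtype=int)
    shrinkage_used = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # collinearity warnings
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            try:
                clf = LinearDiscriminantAnalysis(solver="svd")
                clf.fit(x[mask], y[mask])
            except (np.linalg.LinAlgError, IndexError, ZeroDivisionError):
                # degenerate / singular within-class covariance
                # singular within-class covariance: regularize
                clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                clf.fit(x[mask], y[mask])
                shrinkage_used = True
            pred[i] = clf.predict(x[i:i + 1])[0]
    if shrinkage_used:
        logging.getLogger(__name__).info("LDA fell back to shrinkage "
                                         "regularization (singular covariance)")
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return matthews_cc(tp, tn, fp, fn)


def select_best_subset(features: pd.DataFrame, labels: pd.Series,
                       step: int = SUBSET_STEP,
                       feature_kind: str = "gene") -> MarkerPanel:
    """mRMR-prefix subset search maximizing LOO-LDA MCC.

    Evaluates prefix sizes n, n-step, ... down to >= 1; the maximal-MCC
    subset wins, ties going to the smaller panel.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    ranking = mrmr_rank(features, labels)
    n = len(ranking)
    sizes = list(range(n, 0, -step))
    trace = {}
    for size in sizes:
        trace[size] = loo_lda_mcc(features.loc[ranking[:size]], labels)
    best_size = min(trace, key=lambda s: (-trace[s], s))
    return MarkerPanel(
        feature_kind=feature_kind,
        selected=ranking[:best_size],
        ranking=ranking,
        mcc_trace=trace,
        best_mcc=trace[best_size],
    )


def train_and_roc(panel: MarkerPanel,
                  discovery: pd.DataFrame, labels_discovery: pd.Series,
                  validation: pd.DataFrame, labels_validation: pd.Series) -> MarkerPanel:
    """Fit a linear SVM on the panel features; ROC/AUC on both cohorts."""
    if not panel.selected:
        raise ValueError("empty marker panel")
    y_val = _encode_labels(pd.Series(labels_validation).reindex(validation.columns))
    if len(set(y_val)) < 2:
        raise ValueError("validation cohort has a single class")
    y_disc = _encode_labels(pd.Series(labels_discovery).reindex(discovery.columns))

    x_disc = discovery.loc[panel.selected].to_numpy(float).T
    x_val = validation.loc[panel.selected].to_numpy(float).T
    # abundances live on a ~1e-6 scale; standardize (fit on discovery
    # only) so the SVM margin is meaningful
    model = make_pipeline(StandardScaler(), SVC(kernel="linear"))
    model.fit(x_disc, y_disc)
    panel.model = model
    for name, x, y in (("discovery", x_disc, y_disc), ("validation", x_val, y_val)):
        scores = model.decision_function(x)
        fpr, tpr, thresholds = roc_curve(y, scores)
        panel.roc[name] = (fpr, tpr, thresholds)
        panel.auc[name] = float(auc(fpr, tpr))
    return panel


def roc_frame(panel: MarkerPanel) -> pd.DataFrame:
    """Long-format ROC points for plotting / TSV export."""
    rows = []
    for cohort, (fpr, tpr, thr) in panel.roc.items():
        for f, t, h in zip(fpr, tpr, thr):
            rows.append({"cohort": cohort, "fpr": f, "tpr": t, "threshold": h})
    return pd.DataFrame(rows)
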