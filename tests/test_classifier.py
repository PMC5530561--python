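"""mRMR ranking, LOO-LDA/MCC subset search, SVM + ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from quantmeta.classifier import (loo_lda_mcc, matthews_cc, mrmr_rank,
                                  mutual_information, select_best_subset,
                                  train_and_roc)


def feature_frame(rows, labels01):
    cols = [f"s{i}" for i in range(len(labels01))]
    m = pd.DataFrame(np.atleast_2d(rows), columns=cols)
    m.index = [f"f{i}" for i in range(m.shape[0])]
    labels = pd.Series(np.where(np.asarray(labels01) == 1, "case", "control"),
                       index=cols)
    return m, labels


class TestMutualInformation:
    def test_matches_sklearn(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 3, 40)
            b = rng.integers(0, 4, 40)
            assert mutual_information(a, b) == pytest.approx(
                mutual_info_score(a, b), abs=1e-12)


class TestMRMR:
    def test_perfect_feature_ranked_first(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 15 + [1] * 15)
        rows = rng.normal(size=(10, 30))
        rows[4] = y * 3 + rng.normal(0, 0.05, 30)
        m, labels = feature_frame(rows, y)
        assert mrmr_rank(m, labels)[0] == "f4"

    def test_redundant_copy_penalized(self):
        """Informative feature + identical copy + weaker independent
        feature: the copy must not rank second."""
        rng = np.random.default_rng(2)
        y = np.array([0] * 20 + [1] * 20)
        strong = y * 2.0 + rng.normal(0, 0.1, 40)
        weak = y * 1.0 + rng.normal(0, 1.0, 40)
        m, labels = feature_frame([strong, strong.copy(), weak], y)
        order = mrmr_rank(m, labels)
        assert order[0] in ("f0", "f1")
        assert order[1] == "f2"

    def test_full_selection_is_permutation(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 20)
        m, labels = feature_frame(rng.normal(size=(7, 20)), y)
        assert sorted(mrmr_rank(m, labels)) == sorted(m.index)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 24)
        m, labels = feature_frame(rng.normal(size=(12, 24)), y)
        assert mrmr_rank(m, labels) == mrmr_rank(m, labels)


class TestMCC:
    @pytest.mark.parametrize("tp,tn,fp,fn,expected", [
        (3, 3, 1, 1, 0.5),       # (9-1)/sqrt(4^4)
        (5, 5, 0, 0, 1.0),
        (0, 0, 5, 5, -1.0),
        (4, 0, 0, 4, 0.0),       # empty margin
    ])
    def test_direct_formula(self, tp, tn, fp, fn, expected):
        assert matthews_cc(tp, tn, fp, fn) == pytest.approx(expected)

    def test_matches_contingency_definition_enumerated_to_n8(self):
        """Brute force over all 4-cell tables with n <= 8 against the
        sklearn contingency implementation."""
        for n in range(2, 9):
            for tp, tn, fp in itertools.product(range(n + 1), repeat=3):
                fn = n - tp - tn - fp
                if fn < 0:
                    continue
                y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
                y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
                if len(set(y_true)) < 1:
                    continue
                ref = matthews_corrcoef(y_true, y_pred)
                assert matthews_cc(tp, tn, fp, fn) == pytest.approx(ref, abs=1e-12)


class TestLooLda:
    def test_perfectly_separated_mcc_one(self):
        y = np.array([0] * 6 + [1] * 6)
        m, labels = feature_frame([y * 10.0 + np.arange(12) * 0.01], y)
        assert loo_lda_mcc(m, labels) == pytest.approx(1.0)

    def test_label_inversion_antisymmetry_of_mcc(self):
        """Holding predictions fixed, inverting the true labels swaps
        TP<->FN and TN<->FP and negates the MCC."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 6, size=4)
            assert matthews_cc(tp, tn, fp, fn) == pytest.approx(
                -matthews_cc(fn, fp, tn, tp))

    def test_tiny_class_rejected(self):
        m, labels = feature_frame([[1.0, 2.0, 3.0]], [0, 0, 1])
        with pytest.raises(ValueError):
            loo_lda_mcc(m, labels)


class TestSubsetSearch:
    def test_subset_sizes_by_step(self):
        rng = np.random.default_rng(6)
        y = np.array([0] * 10 + [1] * 10)
        m, labels = feature_frame(rng.normal(size=(20, 20)), y)
        panel = select_best_subset(m, labels, step=5)
        assert sorted(panel.mcc_trace) == [5, 10, 15, 20]

    def test_step_one_evaluates_all_prefixes(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 8 + [1] * 8)
        m, labels = feature_frame(rng.normal(size=(6, 16)), y)
        panel = select_best_subset(m, labels, step=1)
        assert sorted(panel.mcc_trace) == [1, 2, 3, 4, 5, 6]

    def test_informative_feature_kept_and_best_mcc_is_max(self):
        rng = np.random.default_rng(8)
        y = np.array([0] * 12 + [1] * 12)
        rows = rng.normal(size=(10, 24))
        rows[3] = y * 4 + rng.normal(0, 0.2, 24)
        m, labels = feature_frame(rows, y)
        panel = select_best_subset(m, labels, step=1)
        assert "f3" in panel.selected
        assert panel.best_mcc == max(panel.mcc_trace.values())

    def test_mcc_tie_prefers_smaller_panel(self):
        y = np.array([0] * 6 + [1] * 6)
        perfect = y * 5.0
        m, labels = feature_frame([perfect, perfect * 0.9], y)
        panel = select_best_subset(m, labels, step=1)
        assert len(panel.selected) == 1


class TestRoc:
    def make_cohorts(self, separation, seed=0, n_train=40, n_val=20):
        rng = np.random.default_rng(seed)
        y_d = np.array([0, 1] * (n_train // 2))
        y_v = np.array([0, 1] * (n_val // 2))
        x_d = separation * y_d + rng.normal(0, 1, n_train)
        x_v = separation * y_v + rng.normal(0, 1, n_val)
        m_d, lab_d = feature_frame([x_d], y_d)
        m_v, lab_v = feature_frame([x_v], y_v)
        m_v.columns = [f"v{i}" for i in range(n_val)]
        lab_v.index = m_v.columns
        return m_d, lab_d, m_v, lab_v

    def test_perfect_separation_auc_one(self):
        m_d, lab_d, m_v, lab_v = self.make_cohorts(separation=50.0)
        panel = select_best_subset(m_d, lab_d, step=1)
        panel = train_and_roc(panel, m_d, lab_d, m_v, lab_v)
        assert panel.auc["discovery"] == pytest.approx(1.0)
        assert panel.auc["validation"] == pytest.approx(1.0)

    def test_auc_equals_rank_sum_estimator(self):
        """Trapezoid AUC on tie-free scores equals the Mann-Whitney
        probability estimate P(score_case > score_control)."""
        m_d, lab_d, m_v, lab_v = self.make_cohorts(separation=1.0, seed=9)
        panel = select_best_subset(m_d, lab_d, step=1)
        panel = train_and_roc(panel, m_d, lab_d, m_v, lab_v)
        scores = panel.model.decision_function(m_v.to_numpy().T)
        y = (lab_v == "case").to_numpy()
        u = stats.mannwhitneyu(scores[y], scores[~y]).statistic
        assert panel.auc["validation"] == pytest.approx(
            u / (y.sum() * (~y).sum()), abs=1e-9)

    def test_one_class_validation_rejected(self):
        m_d, lab_d, m_v, lab_v = self.make_cohorts(separation=1.0)
        lab_v[:] = "case"
        panel = select_best_subset(m_d, lab_d, step=1)
        with pytest.raises(ValueError):
            train_and_roc(panel, m_d, lab_d, m_v, lab_v)

    def test_validation_labels_never_influence_selection(self):
        """Leakage check: permuting validation labels leaves the selected
        panel identical."""
        rng = np.random.default_rng(10)
        y = np.array([0] * 15 + [1] * 15)
        rows = rng.normal(size=(8, 30))
        rows[2] = y * 3 + rng.normal(0, 0.3, 30)
        m_d, lab_d = feature_frame(rows, y)
        panel_a = select_best_subset(m_d, lab_d, step=1)
        panel_b = select_best_subset(m_d, lab_d, step=1)
        assert panel_a.selected == panel_b.selected  # no hidden state at all
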