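"""Cross-validation protocol, metrics, and concatenated-fold ROC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import confusion_matrix

from fogpet.cv import (classification_metrics, concat_global_roc, make_folds,
                       regression_metrics, roc_auc_corrected, run_cv, select_task)
from fogpet.synthetic import SubjectRecord

from _oracles import pairwise_auc


class TestMakeFolds:
    def test_even_partition(self):
        plan = make_folds(list(range(20)), k=10, seed=0)
        assert all(len(f) == 2 for f in plan.folds)

    def test_46_subjects_sizes_differ_by_at_most_one(self):
        plan = make_folds(list(range(46)), k=10, seed=1)
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes == [4, 4, 4, 4, 5, 5, 5, 5, 5, 5]

    def test_disjoint_and_covering(self):
        plan = make_folds([f"s{i}" for i in range(23)], k=10, seed=2)
        seen = [s for f in plan.folds for s in f]
        assert sorted(seen) == sorted(f"s{i}" for i in range(23))

    def test_inner_split_disjoint_and_stratified(self):
        ids = list(range(30))
        labels = [i % 2 for i in ids]
        plan = make_folds(ids, k=5, seed=3, labels=labels)
        for f in range(5):
            train, val = plan.inner[f]
            assert not set(train) & set(val)
            assert not set(plan.folds[f]) & (set(train) | set(val))
            val_labels = {labels[ids.index(s)] for s in val}
            assert val_labels == {0, 1}

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            make_folds(list(range(5)), k=10, seed=0)

    @given(n=st.integers(10, 60), k=st.integers(2, 10), seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_plan_invariants(self, n, k, seed):
        if n < k:
            return
        plan = make_folds(list(range(n)), k=k, seed=seed)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(s for f in plan.folds for s in f) == list(range(n))
        for (train, val), test in zip(plan.inner, plan.folds):
            assert not set(train) & set(val)
            assert set(train) | set(val) == set(range(n)) - set(test)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        m = classification_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == (100, 100, 100, 100)

    def test_hand_computed_confusion(self):
        # TP=3, FP=1, FN=1, TN=5
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = classification_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(80.0)
        assert m["precision"] == pytest.approx(75.0)
        assert m["recall"] == pytest.approx(75.0)
        assert m["f1"] == pytest.approx(75.0)

    def test_no_positive_predictions_flagged_not_zero(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            m = classification_metrics([0, 1], [0, 0])
        assert np.isnan(m["precision"])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])

    def test_agrees_with_sklearn_confusion_matrix(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_true = rng.integers(0, 2, size=30)
            y_pred = rng.integers(0, 2, size=30)
            if y_pred.sum() == 0 or y_true.sum() == 0:
                continue
            m = classification_metrics(y_true, y_pred)
            tn, fp, fn, tp = confusion_matrix(y_true, y_pred).ravel()
            assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (tp, fp, fn, tn)
            assert m["accuracy"] == pytest.approx(100 * (tp + tn) / 30)


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, inv = roc_auc_corrected([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0 and not inv

    def test_inverted_ranking_corrected(self):
        auc, inv = roc_auc_corrected([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0 and inv

    def test_partial_ranking(self):
        auc, inv = roc_auc_corrected([0, 1, 0, 1], [0.2, 0.3, 0.4, 0.5])
        assert auc == pytest.approx(0.75) and not inv

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc_corrected([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            auc, inv = roc_auc_corrected(y, scores)
            raw = pairwise_auc(y, scores)
            assert auc == pytest.approx(max(raw, 1 - raw), abs=1e-10)
            assert inv == (raw < 0.5)

    def test_reported_auc_never_below_half(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = np.r_[np.zeros(5), np.ones(5)].astype(int)
            auc, _ = roc_auc_corrected(y, rng.normal(size=10))
            assert auc >= 0.5


class TestRegressionMetrics:
    def test_exact_prediction_gives_zeros(self):
        y = np.arange(6.0)
        out = regression_metrics(y, y, [0, 0, 0, 1, 1, 1])
        assert (out[["mse", "mae", "rmse"]].to_numpy() == 0).all()

    def test_hand_computed_single_fold(self):
        out = regression_metrics([0.0, 0.0], [1.0, -2.0], [0, 0])
        row = out.iloc[0]
        assert row.mse == pytest.approx(2.5)
        assert row.mae == pytest.approx(1.5)
        assert row.rmse == pytest.approx(np.sqrt(2.5))

    def test_rmse_is_sqrt_mse_per_fold(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        p = y + rng.normal(size=30)
        folds = rng.integers(0, 5, size=30)
        out = regression_metrics(y, p, folds)
        np.testing.assert_allclose(out.rmse, np.sqrt(out.mse), rtol=1e-12)


class TestConcatGlobalRoc:
    def test_two_perfect_folds_pool_to_one(self):
        scores = {0: {"a": 0.9, "b": 0.1}, 1: {"c": 0.8, "d": 0.2}}
        labels = {0: {"a": 1, "b": 0}, 1: {"c": 1, "d": 0}}
        fpr, tpr, auc, inv = concat_global_roc(scores, labels)
        assert auc == 1.0 and not inv

    def test_duplicate_subject_rejected(self):
        scores = {0: {"a": 0.9}, 1: {"a": 0.8, "b": 0.1}}
        labels = {0: {"a": 1}, 1: {"a": 1, "b": 0}}
        with pytest.raises(ValueError, match="more than one fold"):
            concat_global_roc(scores, labels)

    def test_equals_corrected_auc_of_concatenation(self):
        rng = np.random.default_rng(3)
        sids = [f"s{i}" for i in range(20)]
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        sc = rng.normal(size=20)
        scores = {f: {s: sc[i] for i, s in enumerate(sids) if i % 4 == f} for f in range(4)}
        labels = {f: {s: int(y[i]) for i, s in enumerate(sids) if i % 4 == f} for f in range(4)}
        _, _, auc, inv = concat_global_roc(scores, labels)
        ref_auc, ref_inv = roc_auc_corrected(y, sc)
        assert auc == pytest.approx(ref_auc) and inv == ref_inv

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(4)
        sids = [f"s{i}" for i in range(16)]
        y = {s: int(i % 2) for i, s in enumerate(sids)}
        sc = {s: float(rng.normal()) for s in sids}
        folds1 = {0: sids[:8], 1: sids[8:]}
        folds2 = {0: sids[::2], 1: sids[1::2]}
        aucs = []
        for folds in (folds1, folds2):
            scores = {f: {s: sc[s] for s in ss} for f, ss in folds.items()}
            labels = {f: {s: y[s] for s in ss} for f, ss in folds.items()}
            aucs.append(concat_global_roc(scores, labels)[2])
        assert aucs[0] == pytest.approx(aucs[1])


def _records():
    recs = []
    for i in range(6):
        recs.append(SubjectRecord(id=f"h{i}", group="HC", fogq=0, updrs3=1, ledd=0))
    for i in range(5):
        recs.append(SubjectRecord(id=f"n{i}", group="PD-NFOG", fogq=2, updrs3=12, ledd=150))
    for i in range(7):
        recs.append(SubjectRecord(id=f"f{i}", group="PD-FOG", fogq=11, updrs3=20, ledd=300))
    return recs


class TestSelectTask:
    def test_pd_vs_hc_uses_all(self):
        idx, y = select_task(_records(), "pd_vs_hc")
        assert len(idx) == 18 and y.sum() == 12

    def test_fog_vs_nfog_uses_pd_only(self):
        idx, y = select_task(_records(), "fog_vs_nfog")
        assert len(idx) == 12 and y.sum() == 7

    def test_regression_targets_are_fogq(self):
        idx, y = select_task(_records(), "fogq_regress")
        assert len(idx) == 12 and set(y) == {2.0, 11.0}

    def test_unknown_task_raises(self):
        with pytest.raises(ValueError):
            select_task(_records(), "nope")


class _OracleModel:
    """Scores equal to the true labels: a perfect classifier."""

    def __init__(self, label_of):
        self.label_of = label_of

    def fit(self, vols, y, vols_val, y_val, seed=0):
        return self

    def predict_scores(self, vols):
        return np.array([self.label_of[id(v)] for v in vols], dtype=float)

    def predict_labels(self, vols):
        return np.array([self.label_of[id(v)] for v in vols])


class TestRunCv:
    def test_oracle_model_scores_perfectly(self):
        rng = np.random.default_rng(0)
        vols = [rng.normal(size=(4, 4, 4)) for _ in range(20)]
        y = np.array([i % 2 for i in range(20)])
        label_of = {id(v): int(y[i]) for i, v in enumerate(vols)}
        rep = run_cv(vols, y, lambda s: _OracleModel(label_of), k=10, seed=0)
        for metric in ("accuracy", "precision", "recall", "f1"):
            mean, sd = rep.aggregate[metric]
            assert mean == pytest.approx(100.0) and sd == 0.0
        assert rep.auc == 1.0 and not rep.inversion_applied

    def test_three_fold_toy_aggregation_matches_hand_values(self):
        # folds engineered so per-fold accuracies are 100, 50, 50
        class Fixed:
            def fit(self, *a, **k):
                return self

            def predict_scores(self, vols):
                return np.array([v[0, 0, 0] for v in vols])

            def predict_labels(self, vols):
                return (np.array([v[0, 0, 0] for v in vols]) > 0.5).astype(int)

        vols, y = [], []
        rng = np.random.default_rng(1)
        plan_ids = list(range(12))
        plan = make_folds(plan_ids, k=3, seed=5, labels=[i % 2 for i in plan_ids])
        flips = {0: 0, 1: 1, 2: 1}  # number of wrong test subjects per fold
        for i in plan_ids:
            vols.append(np.zeros((2, 2, 2)))
        y = np.array([i % 2 for i in plan_ids])
        for f, ids in enumerate(plan.folds):
            wrong = flips[f]
            for j, sid in enumerate(ids):
                truth = y[sid]
                pred = 1 - truth if j < wrong else truth
                vols[sid][0, 0, 0] = pred
        rep = run_cv(vols, y, lambda s: Fixed(), k=3, seed=5)
        accs = sorted(rep.per_fold.accuracy)
        mean, sd = rep.aggregate["accuracy"]
        assert mean == pytest.approx(np.mean(accs))
        assert sd == pytest.approx(np.std(accs, ddof=1))
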