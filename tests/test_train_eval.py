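"""Metrics vs independent oracles, fold mechanics, schedule, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindlecnn.model import CNNSpec, build_model
from spindlecnn.train_eval import (
    TrainConfig,
    compute_metrics,
    cross_validate,
    learning_rate_at,
    make_folds,
    train,
)


def brute_force_metrics(labels, predicted, scores):
    """Independent oracle: explicit loops over samples and pairs."""
    tp = fp = tn = fn = 0
    for lab, pred in zip(labels, predicted):
        if lab == 1 and pred == 1:
            tp += 1
        elif lab == 1 and pred == 0:
            fn += 1
        elif lab == 0 and pred == 1:
            fp += 1
        else:
            tn += 1
    acc = (tp + tn) / len(labels)
    rec = tp / (tp + fn)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    wins = ties = 0
    pos = [s for lab, s in zip(labels, scores) if lab == 1]
    neg = [s for lab, s in zip(labels, scores) if lab == 0]
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    auc = (wins + 0.5 * ties) / (len(pos) * len(neg))
    return acc, rec, f1, prec, auc


class TestMetrics:
    def test_worked_confusion_example(self):
        """TP=45 FN=5 FP=10 TN=40: acc .85, rec .90, prec .8182, F1 .8571."""
        labels = np.r_[np.ones(50), np.zeros(50)]
        predicted = np.r_[np.ones(45), np.zeros(5), np.ones(10), np.zeros(40)]
        scores = predicted  # scores irrelevant to the four counts
        m = compute_metrics(labels, predicted, scores)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["recall"] == pytest.approx(0.90)
        assert m["precision"] == pytest.approx(45 / 55)
        assert m["f1"] == pytest.approx(2 * (45 / 55) * 0.9 / ((45 / 55) + 0.9))
        assert (m["TP"], m["FP"], m["TN"], m["FN"]) == (45, 10, 40, 5)

    def test_auc_perfect_ranking(self):
        m = compute_metrics([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.4, 0.3])
        assert m["auc"] == 1.0

    def test_auc_all_ties_is_half(self):
        m = compute_metrics([1, 1, 0, 0], [1, 1, 1, 1], [0.7] * 4)
        assert m["auc"] == 0.5

    def test_random_sets_match_brute_force_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = 200
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # force ties
            predicted = (scores >= 0.5).astype(int)
            m = compute_metrics(labels, predicted, scores)
            acc, rec, f1, prec, auc = brute_force_metrics(labels, predicted, scores)
            assert m["accuracy"] == acc
            assert m["recall"] == rec
            assert m["precision"] == prec
            assert m["f1"] == f1
            assert m["auc"] == pytest.approx(auc, abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import f1_score, roc_auc_score

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 300)
        scores = rng.random(300)
        predicted = (scores >= 0.5).astype(int)
        m = compute_metrics(labels, predicted, scores)
        assert m["auc"] == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert m["f1"] == pytest.approx(f1_score(labels, predicted), abs=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 1), st.integers(0, 4)), min_size=2, max_size=12,
    ))
    def test_auc_equals_pairwise_probability_small_n(self, pairs):
        labels = np.array([p[0] for p in pairs])
        scores = np.array([p[1] / 4 for p in pairs])
        if labels.sum() in (0, len(labels)):
            return
        predicted = (scores >= 0.5).astype(int)
        m = compute_metrics(labels, predicted, scores)
        *_, auc = brute_force_metrics(labels, predicted, scores)
        assert m["auc"] == pytest.approx(auc, abs=1e-12)

    def test_no_positives_raises(self):
        with pytest.raises(ValueError, match="recall undefined"):
            compute_metrics([0, 0], [0, 1], [0.1, 0.9])


class TestSchedule:
    def test_closed_form_values(self):
        cfg = TrainConfig()
        expected = [0.1, 0.1, 0.1, 0.075, 0.075, 0.075, 0.05625]
        assert [learning_rate_at(cfg, e) for e in range(7)] == pytest.approx(expected)

    def test_logged_lr_matches_closed_form(self, tiny_train_data):
        X, y = tiny_train_data
        cfg = TrainConfig(epochs=7, seed=0)
        model = build_model(CNNSpec(), seed=0)
        log = []
        train(model, X, y, cfg, log=log)
        assert [e["lr"] for e in log] == [
            learning_rate_at(cfg, e) for e in range(7)
        ]


class TestFolds:
    def make_ws(self, n_subjects=20, per_subject=10):
        from spindlecnn.windowing import Window, WindowSet

        wins = []
        for s in range(n_subjects):
            for i in range(per_subject):
                wins.append(Window(np.zeros(30), i % 2, f"S{s:02d}", "C3", float(i)))
        return WindowSet(wins)

    def test_subject_partition_sizes(self):
        ws = self.make_ws(20)
        folds = make_folds(ws, k=5, grouping="by_subject", seed=0)
        assert len(folds) == 5
        for train_idx, test_idx in folds:
            test_subjects = set(ws.subject_id[test_idx])
            assert len(test_subjects) == 4
            assert not test_subjects & set(ws.subject_id[train_idx])

    def test_test_folds_partition_all_windows(self):
        ws = self.make_ws(10)
        for grouping in ("by_subject", "by_window"):
            folds = make_folds(ws, k=5, grouping=grouping, seed=1)
            all_test = np.concatenate([t for _, t in folds])
            assert sorted(all_test) == list(range(len(ws)))

    def test_same_seed_same_folds(self):
        ws = self.make_ws(10)
        f1 = make_folds(ws, seed=3)
        f2 = make_folds(ws, seed=3)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_too_few_subjects_rejected(self):
        ws = self.make_ws(3)
        with pytest.raises(ValueError, match="subject"):
            make_folds(ws, k=5, grouping="by_subject")


class TestTraining:
    def test_learns_separable_toy_problem(self, tiny_train_data):
        X, y = tiny_train_data
        model = build_model(CNNSpec(), seed=1)
        log = []
        train(model, X, y, TrainConfig(epochs=6, seed=1), log=log)
        assert log[-1]["train_accuracy"] >= 0.99

    def test_deterministic_final_parameters(self, tiny_train_data):
        X, y = tiny_train_data
        states = []
        for _ in range(2):
            model = build_model(CNNSpec(), seed=2)
            train(model, X, y, TrainConfig(epochs=2, seed=2))
            states.append(model.net.state())
        for k in states[0]:
            np.testing.assert_array_equal(states[0][k], states[1][k])


class TestCrossValidate:
    def test_report_structure_and_recomputation(self, small_window_set):
        report = cross_validate(
            small_window_set, CNNSpec(),
            TrainConfig(epochs=2, seed=0), k=3,
        )
        assert len(report.per_fold) == 3
        df = report.to_dataframe()
        assert len(df) == 4  # 3 folds + aggregate
        for fold in report.per_fold:
            for m in ("accuracy", "recall", "f1", "precision", "auc"):
                assert 0.0 <= fold[m] <= 1.0
        # metrics recomputed from persisted predictions match the report
        for fold_rec, fold_metrics in zip(report.predictions, report.per_fold):
            m = compute_metrics(
                fold_rec["y"], (fold_rec["scores"] >= 0.5).astype(int),
                fold_rec["scores"],
            )
            assert m["accuracy"] == fold_metrics["accuracy"]
            assert m["auc"] == fold_metrics["auc"]
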