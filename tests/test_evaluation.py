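"""Metric formulas against brute-force and sklearn oracles."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from _oracles import (
    accuracy_bf,
    auc_bf,
    average_precision_bf,
    map_bf,
    prf1_bf,
    random_score_set,
    top5_bf,
)
from birdcall.evaluation import (
    ConfusionCounts,
    ScoreSet,
    accuracy,
    auc_pairwise,
    average_precision,
    confusion_counts,
    evaluate_scores,
    macro_micro_auc,
    map_score,
    pca_embed,
    prf1,
    roc_auc_trapezoid,
    roc_curve,
    top5_accuracy,
)


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion_counts([0, 1, 2], [0, 1, 2])
        for tp, fp, fn, _ in c.counts.values():
            assert fp == 0 and fn == 0 and tp == 1

    def test_hand_counted_example(self):
        c = confusion_counts(["B", "B", "B"], ["A", "A", "A"],
                             labels=["A", "B"])
        assert c.counts["A"] == (0, 0, 3, 0)
        assert c.counts["B"] == (0, 3, 0, 0)

    def test_counts_sum_to_n(self, rng):
        pred = rng.integers(0, 4, size=40)
        truth = rng.integers(0, 4, size=40)
        c = confusion_counts(pred, truth, labels=np.arange(4))
        for counts in c.counts.values():
            assert sum(counts) == 40

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([0, 5], [0, 1], labels=[0, 1])


class TestPRF1:
    def test_hand_arithmetic(self):
        table = prf1(ConfusionCounts({"x": (8, 2, 2, 88)}))
        assert np.isclose(table.loc["x", "precision"], 0.8)
        assert np.isclose(table.loc["x", "recall"], 0.8)
        assert np.isclose(table.loc["x", "f1"], 0.8)

    def test_degenerate_class_reports_zero(self):
        with pytest.warns(UserWarning):
            table = prf1(ConfusionCounts({"x": (0, 0, 0, 10)}))
        assert (table.loc["x"] == 0).all()

    def test_f1_bounded_by_components(self, rng):
        for _ in range(20):
            tp, fp, fn = rng.integers(0, 20, size=3)
            table = prf1(ConfusionCounts({"x": (int(tp), int(fp), int(fn), 5)}))
            row = table.loc["x"]
            assert row["f1"] <= max(row["precision"], row["recall"]) + 1e-12


class TestTopK:
    def test_perfect_scores(self, rng):
        scores = np.eye(6)[rng.integers(0, 6, size=10)] * 0.9 + 0.01
        truths = scores.argmax(axis=1)
        s = ScoreSet(scores, truths)
        assert accuracy(scores.argmax(axis=1), truths) == 1.0
        assert top5_accuracy(s) == 1.0

    def test_truth_ranked_third_counts_for_top5_only(self):
        scores = np.tile([0.3, 0.25, 0.2, 0.15, 0.07, 0.03], (4, 1))
        truths = np.full(4, 2)
        s = ScoreSet(scores, truths)
        assert accuracy(scores.argmax(axis=1), truths) == 0.0
        assert top5_accuracy(s) == 1.0

    def test_matches_sort_and_check_oracle(self, rng):
        scores, truths = random_score_set(rng, n_max=20, k_max=8)
        while scores.shape[1] < 5:
            scores, truths = random_score_set(rng, n_max=20, k_max=8)
        s = ScoreSet(scores, truths)
        assert top5_accuracy(s) == top5_bf(scores, truths)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            top5_accuracy(ScoreSet(np.ones((3, 4)) / 4, np.zeros(3, int)))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_pairwise([0.1, 0.2, 0.8, 0.9],
                            [False, False, True, True]) == 1.0

    def test_identical_scores_half_with_ties_zero_strict(self):
        scores = [0.5] * 6
        flags = [True, False, True, False, True, False]
        assert auc_pairwise(scores, flags) == 0.5
        assert auc_pairwise(scores, flags, strict=True) == 0.0

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(6, 30)
            scores = rng.random(n)
            flags = np.r_[True, False, rng.random(n - 2) < 0.4]
            got = auc_pairwise(scores, flags)
            assert abs(got - roc_auc_score(flags, scores)) < 1e-10

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            auc_pairwise([0.1, 0.9], [True, True])


class TestAveragePrecision:
    def test_positives_on_top(self):
        s = ScoreSet(np.array([[0.9], [0.8], [0.2], [0.1]]),
                     np.array([0, 0, 1, 1]))
        assert average_precision(s, 0) == 1.0

    def test_hand_evaluated_staircase(self):
        """Scores (.9,.8,.7,.6) with truths (+,-,+,-): AP = 1*(1/2) + (2/3)*(1/2)."""
        scores = np.array([[0.9], [0.8], [0.7], [0.6]])
        truths = np.array([0, 1, 0, 1])
        s = ScoreSet(scores, truths)
        assert np.isclose(average_precision(s, 0), 5.0 / 6.0)

    def test_map_is_mean_of_aps(self, rng):
        scores, truths = random_score_set(rng)
        s = ScoreSet(scores, truths)
        aps = [average_precision(s, k) for k in range(scores.shape[1])]
        assert np.isclose(map_score(s), np.mean(aps))

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(50):
            scores, truths = random_score_set(rng)
            s = ScoreSet(scores, truths)
            for k in range(scores.shape[1]):
                ref = average_precision_score(truths == k, scores[:, k])
                assert abs(average_precision(s, k) - ref) < 1e-10


class TestROC:
    def test_endpoints_and_perfect_separation(self):
        pts = roc_curve([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert (0.0, 1.0) in pts

    def test_monotone(self, rng):
        scores = rng.random(25)
        flags = np.r_[True, False, rng.random(23) < 0.5]
        pts = np.array(roc_curve(scores, flags))
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_micro_average_area_matches_micro_auc(self, rng):
        from birdcall.evaluation import micro_average_roc

        scores, truths = random_score_set(rng)
        s = ScoreSet(scores, truths)
        _, micro = macro_micro_auc(s)
        area = roc_auc_trapezoid(micro_average_roc(s))
        assert abs(area - micro) < 1e-10

    def test_macro_average_curve_is_monotone_unit_span(self, rng):
        from birdcall.evaluation import macro_average_roc

        scores, truths = random_score_set(rng)
        pts = np.array(macro_average_roc(ScoreSet(scores, truths)))
        assert pts[0, 0] == 0.0 and pts[-1, 0] == 1.0
        assert (np.diff(pts[:, 1]) >= -1e-12).all()
        assert np.isclose(pts[-1, 1], 1.0)

    def test_area_equals_pairwise_auc(self, rng):
        for _ in range(30):
            n = rng.integers(6, 30)
            scores = np.round(rng.random(n), 2)  # force some ties
            flags = np.r_[True, False, rng.random(n - 2) < 0.5]
            area = roc_auc_trapezoid(roc_curve(scores, flags))
            assert abs(area - auc_pairwise(scores, flags)) < 1e-10


class TestPCA:
    def test_collinear_points_have_flat_second_component(self):
        base = np.outer(np.arange(10.0), np.ones(6))
        coords = pca_embed(list(base))
        assert coords.shape == (10, 2)
        assert coords[:, 1].var() < 1e-12

    def test_600_samples_shape(self, rng):
        mats = [rng.normal(size=(8, 12)) for _ in range(600)]
        coords = pca_embed(mats)
        assert coords.shape == (600, 2)
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(40, 7))
        coords = pca_embed(list(X))
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        ref = Xc @ evecs[:, ::-1][:, :2]
        for j in range(2):  # eigenvectors are sign-ambiguous
            assert (np.allclose(coords[:, j], ref[:, j], atol=1e-8)
                    or np.allclose(coords[:, j], -ref[:, j], atol=1e-8))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_embed([rng.normal(size=4), rng.normal(size=4)])


class TestEvaluateScores:
    def test_oracle_scores_score_perfectly(self):
        truths = np.arange(6).repeat(3)
        scores = np.eye(6)[truths] * 0.94 + 0.01
        rep = evaluate_scores(scores, truths)
        assert rep.accuracy == rep.f1 == rep.map_score == 1.0
        assert rep.top5_accuracy == 1.0

    def test_uniform_random_scores_near_chance(self):
        rng = np.random.default_rng(0)
        n, k = 400, 8
        scores = rng.random((n, k))
        scores /= scores.sum(axis=1, keepdims=True)
        truths = rng.integers(0, k, size=n)
        rep = evaluate_scores(scores, truths)
        se = np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(rep.accuracy - 1 / k) <= 3 * se

    def test_all_rates_within_unit_interval(self, rng):
        scores, truths = random_score_set(rng)
        rep = evaluate_scores(scores, truths)
        for name in ("accuracy", "precision", "recall", "f1", "auc",
                     "map_score", "micro_auc"):
            assert 0.0 <= getattr(rep, name) <= 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_scores(np.zeros((0, 5)), np.zeros(0, int))


def test_all_metrics_match_brute_force_on_random_score_sets(rng):
    """Every metric agrees with an independent loop-based implementation
    on 50 random small score sets to < 1e-10."""
    for _ in range(50):
        scores, truths = random_score_set(rng)
        k = scores.shape[1]
        pred = scores.argmax(axis=1)
        assert abs(accuracy(pred, truths) - accuracy_bf(pred, truths)) < 1e-10
        c = confusion_counts(pred, truths, labels=np.arange(k))
        table = prf1(c)
        for lab in range(k):
            p_ref, r_ref, f_ref = prf1_bf(pred, truths, lab)
            assert abs(table.loc[lab, "precision"] - p_ref) < 1e-10
            assert abs(table.loc[lab, "recall"] - r_ref) < 1e-10
            assert abs(table.loc[lab, "f1"] - f_ref) < 1e-10
            flags = truths == lab
            if flags.any() and (~flags).any():
                assert abs(auc_pairwise(scores[:, lab], flags)
                           - auc_bf(scores[:, lab].tolist(), flags.tolist())) < 1e-10
        s = ScoreSet(scores, truths)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert abs(map_score(s) - map_bf(scores, truths)) < 1e-10
        if k >= 5:
            assert abs(top5_accuracy(s) - top5_bf(scores, truths)) < 1e-10


def test_micro_average_accuracy_is_printed_accuracy(rng):
    """The micro-averaged correct/total ratio equals the printed Accuracy."""
    scores, truths = random_score_set(rng)
    rep = evaluate_scores(scores, truths)
    pred = scores.argmax(axis=1)
    assert rep.accuracy == np.mean(pred == truths)
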