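"""Oversampling, splits, the weighted ensemble, evaluation metrics,
importance ranks and the rank-based carry-forward rule."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from s2mr.predictive import (EnsembleModel, classify_cfe_predictive,
                             evaluate_metrics, fit_ensemble, lopo_folds,
                             majority_baseline, predict_and_evaluate,
                             random_baseline, rank_feature_importance,
                             smote_balance)


class TestSmote:
    def test_rebalances_five_to_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (50, 3))])
        y = np.array(["wrong"] * 10 + ["right"] * 50)
        Xa, ya = smote_balance(X, y, rng)
        assert (ya == "wrong").sum() == (ya == "right").sum() == 50
        # originals preserved
        np.testing.assert_array_equal(Xa[:60], X)

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20, 2))
        y = np.array(["right", "wrong"] * 10)
        Xa, ya = smote_balance(X, y, rng)
        assert Xa is X and ya is y

    def test_minority_too_small_raises(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (24, 2))
        y = np.array(["wrong"] * 4 + ["right"] * 20)
        with pytest.raises(ValueError, match="pool"):
            smote_balance(X, y, rng)

    def test_synthetic_points_match_neighbour_mean_construction(self):
        """Every synthetic point equals the mean of its source point's 4
        nearest minority neighbours jittered by +-25/50 % of their SD
        (independent k-NN oracle), hence lies in the expanded bbox."""
        rng = np.random.default_rng(3)
        for trial in range(100):
            n_min = int(rng.integers(5, 12))
            X = np.vstack([rng.normal(0, 1, (n_min, 3)),
                           rng.normal(5, 1, (5 * n_min, 3))])
            y = np.array(["wrong"] * n_min + ["right"] * (5 * n_min))
            Xa, ya = smote_balance(X, y, np.random.default_rng(trial))
            synth = Xa[len(X):]
            assert len(synth) == 4 * n_min

            Xm = X[:n_min]
            expected = []
            d = cdist(Xm, Xm)
            np.fill_diagonal(d, np.inf)
            for i in range(n_min):
                four = np.argsort(d[i])[:4]
                mu = Xm[four].mean(axis=0)
                sd = Xm[four].std(axis=0)
                for c in (0.25, -0.25, 0.5, -0.5):
                    expected.append(mu + c * sd)
                lo = Xm[four].min(axis=0) - 0.5 * sd
                hi = Xm[four].max(axis=0) + 0.5 * sd
            expected = np.asarray(expected)
            for s in synth:
                assert np.min(np.linalg.norm(expected - s, axis=1)) < 1e-9


class TestLopoFolds:
    def test_forty_participants(self):
        rng = np.random.default_rng(0)
        ids = [f"P{i:02d}" for i in range(40)]
        holdout, folds = lopo_folds(np.array(ids), rng)
        assert len(holdout) == 4 and len(folds) == 36

    def test_three_participants(self):
        holdout, folds = lopo_folds(np.array(["a", "b", "c"]),
                                    np.random.default_rng(1))
        assert len(holdout) == 1 and len(folds) == 2

    def test_no_participant_on_both_sides(self):
        rng = np.random.default_rng(2)
        ids = np.array([f"P{i}" for i in range(17)])
        holdout, folds = lopo_folds(ids, rng)
        for train, val in folds:
            assert not set(train) & set(val)
            assert not set(train) & set(holdout)
            assert not set(val) & set(holdout)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            lopo_folds(np.array(["a", "b"]), np.random.default_rng(0))


def _blobs(n=30, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(sep, 1, (n, 4))])
    y = np.array(["wrong"] * n + ["right"] * n)
    return X, y


class TestEnsemble:
    def test_weights_sum_to_one(self):
        X, y = _blobs()
        m = fit_ensemble(X, y, X, y, np.random.default_rng(0), smote=False)
        assert m.weights.sum() == pytest.approx(1.0)
        assert np.all(m.weights >= 0)

    def test_separable_blobs_high_holdout_accuracy(self):
        X, y = _blobs(seed=1)
        Xh, yh = _blobs(seed=2)
        m = fit_ensemble(X, y, X, y, np.random.default_rng(0), smote=False)
        ev = predict_and_evaluate(m, Xh, yh)
        acc = (ev.tp + ev.tn) / (ev.tp + ev.tn + ev.fp + ev.fn)
        assert acc > 0.9

    def test_single_class_train_raises(self):
        X = np.random.default_rng(0).normal(0, 1, (20, 3))
        y = np.array(["right"] * 20)
        with pytest.raises(ValueError):
            fit_ensemble(X, y, X, y, np.random.default_rng(0), smote=False)

    def test_missing_features_are_median_imputed(self):
        X, y = _blobs()
        X[0, 0] = np.nan
        m = fit_ensemble(X, y, X, y, np.random.default_rng(0), smote=False)
        assert np.isfinite(m.score(X)).all()


class TestMetrics:
    def test_printed_example(self):
        ev = evaluate_metrics(np.array(["right"] * 5 + ["wrong"]),
                              np.array(["right"] * 6))
        assert ev.tp == 5 and ev.fp == 1 and ev.fn == 0
        assert ev.precision == pytest.approx(5 / 6)
        assert ev.recall == 1.0

    def test_all_correct(self):
        y = np.array(["right", "wrong", "right"])
        ev = evaluate_metrics(y, y)
        assert ev.precision == ev.recall == ev.f1 == 1.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            y = rng.choice(["right", "wrong"], 40)
            p = rng.choice(["right", "wrong"], 40)
            ev = evaluate_metrics(y, p)
            tp = sum(a == b == "right" for a, b in zip(y, p))
            fp = sum(a == "wrong" and b == "right" for a, b in zip(y, p))
            fn = sum(a == "right" and b == "wrong" for a, b in zip(y, p))
            tn = sum(a == b == "wrong" for a, b in zip(y, p))
            assert (ev.tp, ev.fp, ev.fn, ev.tn) == (tp, fp, fn, tn)
            if tp + fp:
                assert ev.precision == pytest.approx(tp / (tp + fp))
            if 2 * tp + fp + fn:
                assert ev.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_majority_baseline_on_imbalanced_labels(self):
        y = np.array(["right"] * 50 + ["wrong"] * 10)
        ev = majority_baseline(y)
        assert round(ev.precision, 2) == 0.83 and ev.recall == 1.0


class _LinearScorer:
    """Deterministic fake member: score from a fixed linear rule."""

    def __init__(self, w):
        self.w = np.asarray(w, float)

    def score01(self, X):
        return (X @ self.w > 0).astype(float)


def _fake_fold(w, X, y):
    model = EnsembleModel(members=[_LinearScorer(w)],
                          weights=np.array([1.0]),
                          medians=np.zeros(X.shape[1]))
    return (model, X, y)


class TestImportance:
    def test_top_set_cutoff_arithmetic(self):
        """140 features at the 10 % fraction cut at rank ceil(14); the
        top flag is exactly 'rank within cutoff and importance > 0'."""
        k = 140
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (300, k))
        w = np.linspace(2.0, 0.1, k)  # every feature informative, graded
        y = np.where(X @ w > 0, "right", "wrong")
        imp = rank_feature_importance([_fake_fold(w, X, y)],
                                      [f"f{i}" for i in range(k)],
                                      np.random.default_rng(1),
                                      top_fraction=0.10)
        cutoff = math.ceil(0.10 * k)
        assert cutoff == 14
        np.testing.assert_array_equal(
            imp["top"], (imp["rank"] <= cutoff) & (imp["importance"] > 0))
        assert imp["rank"].min() == 1

    def test_top_set_size_without_ties(self):
        """With all-distinct importances the top set holds exactly
        ceil(fraction * k) features."""
        rng = np.random.default_rng(2)
        k = 10
        X = rng.normal(0, 1, (400, k))
        w = np.array([3.0, 1.8, 1.1, 0.7, 0.45, 0.3, 0.2, 0.12, 0.07, 0.04])
        y = np.where(X @ w > 0, "right", "wrong")
        imp = rank_feature_importance([_fake_fold(w, X, y)],
                                      [f"f{i}" for i in range(k)],
                                      np.random.default_rng(3),
                                      top_fraction=0.3, n_repeats=3)
        if imp["importance"].nunique() == k:  # distinct -> exact size
            assert imp["top"].sum() == 3
        assert set(imp.loc[imp["rank"] <= 2, "feature"]) <= {"f0", "f1", "f2"}

    def test_noise_feature_ranks_in_bottom_half(self):
        """A pure-noise column ends in the bottom half of the ranking in
        nearly all seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (120, 6))
            w = np.array([1.5, 1.2, 1.0, 0.8, 0.6, 0.0])  # f5 is noise
            y = np.where(X @ w + rng.normal(0, 0.3, 120) > 0, "right", "wrong")
            imp = rank_feature_importance(
                [_fake_fold(w, X, y)], [f"f{i}" for i in range(6)],
                np.random.default_rng(seed), top_fraction=0.5)
            rank_noise = imp.loc[imp["feature"] == "f5", "rank"].iloc[0]
            if rank_noise > 3:
                wins += 1
        assert wins >= 18

    def test_duplicating_a_feature_barely_moves_unrelated_ranks(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (200, 4))
        w = np.array([1.5, 1.0, 0.6, 0.3])
        y = np.where(X @ w > 0, "right", "wrong")
        imp1 = rank_feature_importance([_fake_fold(w, X, y)],
                                       list("abcd"), np.random.default_rng(0),
                                       top_fraction=0.5)
        Xd = np.column_stack([X, X[:, 0]])
        wd = np.append(w, 0.0)
        imp2 = rank_feature_importance([_fake_fold(wd, Xd, y)],
                                       list("abcd") + ["a_dup"],
                                       np.random.default_rng(0),
                                       top_fraction=0.5)
        for f in "bcd":
            r1 = imp1.loc[imp1["feature"] == f, "rank"].iloc[0]
            r2 = imp2.loc[imp2["feature"] == f, "rank"].iloc[0]
            assert r2 <= r1 + 1


class TestPredictiveRule:
    PH = ("see_solve", "move", "respond")

    def _oracle(self, r, top):
        if not all(top):
            return "none"
        if r[0] < r[1] < r[2]:
            return "perfect"
        if r[0] < r[1] and r[0] < r[2] and not (r[1] < r[2]):
            return "pseudo"
        return "none"

    def test_exhaustive_orderings_and_ties(self):
        ranks = [1, 2, 3]
        for r in itertools.product([1, 2, 3], repeat=3):
            for top in itertools.product([True, False], repeat=3):
                got = classify_cfe_predictive(dict(zip(self.PH, map(float, r))),
                                              dict(zip(self.PH, top)))
                assert got == self._oracle(r, top), (r, top)

    def test_worked_rows(self):
        t = dict(zip(self.PH, [True] * 3))
        assert classify_cfe_predictive(dict(zip(self.PH, [5.0, 6.0, 8.0])), t) \
            == "perfect"
        assert classify_cfe_predictive(dict(zip(self.PH, [2.0, 5.0, 4.0])), t) \
            == "pseudo"
        only_ss = dict(zip(self.PH, [True, False, False]))
        assert classify_cfe_predictive(dict(zip(self.PH, [7.0, None, None])),
                                       only_ss) == "none"


def test_random_baseline_is_half_on_balanced_labels():
    rng = np.random.default_rng(0)
    y = np.array(["right", "wrong"] * 50000)
    ev = random_baseline(y, rng)
    for v in (ev.precision, ev.recall, ev.f1):
        assert v == pytest.approx(0.5, abs=0.01)
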