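"""Augmentation, scatter-matrix LDA, GA tuning, and the severity model."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from swemg.model import (DysphagiaSeverityModel, augment_gaussian, ga_tune,
                         lda_reduce)


def gaussian_blobs(n_per_class=40, n_features=6, sep=6.0, seed=0,
                   classes=("none", "mild", "moderate", "severe")):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, cls in enumerate(classes):
        center = np.zeros(n_features)
        center[i % n_features] = sep * (1 + i)
        X.append(rng.standard_normal((n_per_class, n_features)) + center)
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


class TestAugmentation:
    def test_zero_sigma_duplicates_originals(self):
        X, y = gaussian_blobs(5)
        Xa, ya = augment_gaussian(X, y, target_total=40, sigma=0.0, seed=0)
        assert Xa.shape[0] == 40
        originals = {tuple(row) for row in X}
        assert all(tuple(row) in originals for row in Xa)

    def test_target_total_2124_rows(self):
        X, y = gaussian_blobs(10)
        Xa, ya = augment_gaussian(X, y, target_total=2124, seed=1)
        assert Xa.shape[0] == 2124
        # classes balanced
        _, counts = np.unique(ya, return_counts=True)
        assert counts.max() - counts.min() <= 1

    def test_seeded_determinism(self):
        X, y = gaussian_blobs(8)
        a = augment_gaussian(X, y, 200, seed=9)
        b = augment_gaussian(X, y, 200, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_target_below_current_rejected(self):
        X, y = gaussian_blobs(10)
        with pytest.raises(ValueError):
            augment_gaussian(X, y, target_total=10)


class TestLDA:
    def test_four_classes_give_3d(self):
        X, y = gaussian_blobs(30, n_features=10)
        P, proj = lda_reduce(X, y, n_components=3)
        assert P.shape == (X.shape[0], 3)
        assert proj.components.shape[1] <= 3

    def test_two_class_direction_matches_fisher_closed_form(self):
        rng = np.random.default_rng(0)
        n = 500
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        mu1, mu2 = np.array([0.0, 0.0]), np.array([3.0, 1.0])
        X = np.vstack([rng.multivariate_normal(mu1, cov, n),
                       rng.multivariate_normal(mu2, cov, n)])
        y = np.array(["a"] * n + ["b"] * n)
        _, proj = lda_reduce(X, y, n_components=1)
        v = proj.components[:, 0]
        # oracle: w  proportional to  Sw^{-1} (mu2 - mu1), pooled scatter
        Xa, Xb = X[:n], X[n:]
        Sw = ((Xa - Xa.mean(0)).T @ (Xa - Xa.mean(0))
              + (Xb - Xb.mean(0)).T @ (Xb - Xb.mean(0)))
        w = np.linalg.solve(Sw, Xb.mean(0) - Xa.mean(0))
        cos = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_sklearn_projection_separation(self):
        # independent route: class separation in our projection matches
        # sklearn's eigen-solver LDA on the same data
        X, y = gaussian_blobs(40, n_features=8, seed=3)
        P_ours, _ = lda_reduce(X, y, n_components=3)
        P_sk = LinearDiscriminantAnalysis(
            solver="eigen", n_components=3).fit(X, y).transform(X)

        def separation(P):
            grand = P.mean(0)
            classes = np.unique(y)
            b = sum((P[y == c].mean(0) - grand) @ (P[y == c].mean(0) - grand)
                    for c in classes)
            w = sum(np.var(P[y == c], axis=0).sum() for c in classes)
            return b / w
        assert separation(P_ours) == pytest.approx(separation(P_sk), rel=0.05)

    def test_identical_classes_degenerate(self):
        X = np.tile(np.random.default_rng(1).standard_normal((20, 4)), (2, 1))
        y = np.array(["a"] * 20 + ["b"] * 20)
        _, proj = lda_reduce(X, y)
        assert proj.degenerate

    def test_single_class_rejected(self):
        X = np.random.default_rng(2).standard_normal((10, 3))
        with pytest.raises(ValueError):
            lda_reduce(X, np.array(["a"] * 10))


class TestGATuning:
    def test_single_point_space_returns_that_point(self):
        X, y = gaussian_blobs(12, n_features=4)
        space = {"n_estimators": [20], "max_depth": [5],
                 "min_samples_split": [2], "min_samples_leaf": [1]}
        out = ga_tune(X, y, cv_folds=2, seed=0, generations=1, population=2,
                      space=space)
        assert out == {"n_estimators": 20, "max_depth": 5,
                       "min_samples_split": 2, "min_samples_leaf": 1}

    def test_tuned_not_worse_than_untuned(self):
        from swemg.model import DEFAULT_RF_PARAMS, _cv_accuracy
        X, y = gaussian_blobs(15, n_features=4, sep=4.0, seed=5)
        space = {"n_estimators": [10, 30, 50], "max_depth": [3, 5, None],
                 "min_samples_split": [2, 4], "min_samples_leaf": [1, 2]}
        tuned = ga_tune(X, y, cv_folds=2, seed=1, generations=3,
                        population=6, space=space)
        acc_tuned = _cv_accuracy(X, y, tuned, 2, 1)
        acc_default = _cv_accuracy(
            X, y, {**DEFAULT_RF_PARAMS, "n_estimators": 50}, 2, 1)
        assert acc_tuned >= acc_default - 0.01

    def test_reproducible_under_seed(self):
        X, y = gaussian_blobs(10, n_features=3)
        space = {"n_estimators": [10, 20], "max_depth": [3, None],
                 "min_samples_split": [2, 3], "min_samples_leaf": [1, 2]}
        a = ga_tune(X, y, cv_folds=2, seed=7, generations=2, population=4,
                    space=space)
        b = ga_tune(X, y, cv_folds=2, seed=7, generations=2, population=4,
                    space=space)
        assert a == b

    def test_cv_folds_exceeding_class_count_rejected(self):
        X, y = gaussian_blobs(2, n_features=3)
        with pytest.raises(ValueError):
            ga_tune(X, y, cv_folds=5, seed=0)


class TestSeverityModel:
    def test_split_sizes_70_30(self):
        X, y = gaussian_blobs(25)
        res = DysphagiaSeverityModel(X, y, augment_total=0, seed=0).fit(
            tune={"n_estimators": 50, "max_depth": 5,
                  "min_samples_split": 2, "min_samples_leaf": 1})
        assert len(res.test_labels) == 30       # 30% of 100
        assert res.confusion.sum() == 30

    def test_separable_classes_perfect_confusion_diagonal(self):
        X, y = gaussian_blobs(25, sep=10.0)
        res = DysphagiaSeverityModel(X, y, augment_total=0, seed=1).fit(
            tune={"n_estimators": 50, "max_depth": None,
                  "min_samples_split": 2, "min_samples_leaf": 1})
        assert res.accuracy == 1.0
        assert np.all(res.confusion == np.diag(np.diag(res.confusion)))

    def test_probability_rows_sum_to_1(self):
        X, y = gaussian_blobs(20)
        res = DysphagiaSeverityModel(X, y, augment_total=0, seed=2).fit(
            tune={"n_estimators": 30, "max_depth": 5,
                  "min_samples_split": 2, "min_samples_leaf": 1})
        assert np.allclose(res.test_proba.sum(axis=1), 1.0)

    def test_assess_new_subject_nine_trials(self):
        X, y = gaussian_blobs(20, sep=8.0)
        res = DysphagiaSeverityModel(X, y, augment_total=0, seed=3).fit(
            tune={"n_estimators": 30, "max_depth": 5,
                  "min_samples_split": 2, "min_samples_leaf": 1})
        trials = X[y == "severe"][:9]
        report = res.assess_new_subject(trials)
        assert len(report["per_trial_class"]) == 9
        assert sum(report["aggregate_proba"].values()) == pytest.approx(1.0)
        assert report["aggregate_class"] == "severe"
        single = res.assess_new_subject(trials[:1])
        assert np.allclose(list(single["aggregate_proba"].values()),
                           single["per_trial_proba"][0])

    def test_fit_reproducible(self):
        X, y = gaussian_blobs(15)
        kw = dict(tune={"n_estimators": 30, "max_depth": 5,
                        "min_samples_split": 2, "min_samples_leaf": 1})
        r1 = DysphagiaSeverityModel(X, y, augment_total=200, seed=4).fit(**kw)
        r2 = DysphagiaSeverityModel(X, y, augment_total=200, seed=4).fit(**kw)
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.confusion, r2.confusion)
        assert np.array_equal(r1.test_proba, r2.test_proba)

    def test_summary_mentions_key_fields(self):
        X, y = gaussian_blobs(15)
        res = DysphagiaSeverityModel(X, y, augment_total=0, seed=5).fit(
            tune={"n_estimators": 20, "max_depth": 5,
                  "min_samples_split": 2, "min_samples_leaf": 1})
        s = res.summary()
        assert "test accuracy" in s and "confusion matrix" in s
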