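"""LDA/KNN classification and the two evaluation protocols."""

import numpy as np
import pytest

from emgpick import (
    FeatureMatrix,
    accuracy_pct,
    evaluate_cv5,
    evaluate_holdout_half,
    knn_predict,
    lda_predict,
    lda_train,
)
from emgpick.classify import holdout_half_split


def gaussian_blobs(rng, means, n_per_class, sd=1.0):
    X, y = [], []
    for c, m in enumerate(means):
        X.append(rng.standard_normal((n_per_class, len(m))) * sd + np.asarray(m))
        y.append(np.full(n_per_class, c))
    return np.vstack(X), np.concatenate(y)


def as_matrix(X, y, feature_set="td"):
    return FeatureMatrix(
        values=X, labels=y, channel_ids=tuple(range(X.shape[1])), feature_set=feature_set
    )


def test_accuracy_pct_exact_counts():
    assert accuracy_pct(np.array([1, 2, 3, 4]), np.array([1, 2, 0, 0])) == 50.0
    assert accuracy_pct(np.array([1]), np.array([1])) == 100.0


def test_lda_separable_blobs():
    rng = np.random.default_rng(0)
    X, y = gaussian_blobs(rng, [(-5.0, 0.0), (5.0, 0.0)], 200)
    model = lda_train(X, y)
    assert accuracy_pct(lda_predict(model, X), y) >= 99.0


def test_lda_no_signal_is_chance():
    rng = np.random.default_rng(1)
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X, y = gaussian_blobs(rng, [(0.0, 0.0), (0.0, 0.0)], 100)
        Xt, yt = gaussian_blobs(rng, [(0.0, 0.0), (0.0, 0.0)], 100)
        accs.append(accuracy_pct(lda_predict(lda_train(X, y), Xt), yt))
    assert 40.0 <= np.mean(accs) <= 60.0


def test_lda_degenerate_single_point_classes():
    X = np.array([[0.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 1])
    with pytest.warns(UserWarning, match="nearest-class-mean"):
        model = lda_train(X, y)
    np.testing.assert_array_equal(lda_predict(model, X), y)


def test_knn_exact_match_and_cluster_recovery():
    X = np.array([[0.0], [10.0], [0.1], [9.9]])
    y = np.array([0, 1, 0, 1])
    assert knn_predict(X, y, np.array([[0.0]]), k=1)[0] == 0
    test = np.array([[0.05], [9.95]])
    np.testing.assert_array_equal(knn_predict(X, y, test, k=2), [0, 1])


def test_knn_global_vote_ties_to_smallest_label():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 1, 1])
    pred = knn_predict(X, y, np.array([[1.5]]), k=4)
    assert pred[0] == 0


def test_knn_k_guard():
    with pytest.raises(ValueError, match="k="):
        knn_predict(np.zeros((3, 1)), np.array([0, 1, 0]), np.zeros((1, 1)), k=5)


@pytest.mark.parametrize("classifier", ["lda", "knn"])
def test_cv5_separable_features(classifier):
    rng = np.random.default_rng(2)
    X, y = gaussian_blobs(rng, [(-6.0, 0.0), (6.0, 0.0), (0.0, 6.0)], 100)
    res = evaluate_cv5(as_matrix(X, y), classifier=classifier, seed=0)
    assert res.accuracy_pct >= 99.0
    assert res.accuracy_pct == pytest.approx(np.mean(res.per_fold))
    assert len(res.per_fold) == 5


def test_cv5_shuffled_labels_hit_chance():
    rng = np.random.default_rng(3)
    X, y = gaussian_blobs(rng, [(i, 0.0) for i in range(4)], 250, sd=0.1)
    yp = rng.permutation(y)
    res = evaluate_cv5(as_matrix(X, yp), classifier="lda", seed=0)
    assert 17.0 <= res.accuracy_pct <= 33.0  # 4 balanced classes -> 25%


def test_cv5_seeded_determinism():
    rng = np.random.default_rng(4)
    X, y = gaussian_blobs(rng, [(-1.0, 0.0), (1.0, 0.0)], 60)
    a = evaluate_cv5(as_matrix(X, y), seed=42)
    b = evaluate_cv5(as_matrix(X, y), seed=42)
    assert a.per_fold == b.per_fold


def test_cv5_mean_stable_across_seeds():
    rng = np.random.default_rng(5)
    X, y = gaussian_blobs(rng, [(-1.5, 0.0), (1.5, 0.0)], 500)
    fm = as_matrix(X, y)
    means = [evaluate_cv5(fm, seed=s).accuracy_pct for s in range(20)]
    assert np.ptp(means) <= 2.0


def test_cv5_small_class_degrades_to_unstratified():
    X = np.random.default_rng(6).standard_normal((23, 2))
    y = np.array([0] * 20 + [1] * 3)
    with pytest.warns(UserWarning, match="unstratified"):
        evaluate_cv5(as_matrix(X, y), seed=0)


def test_holdout_half_is_per_class_temporal():
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    train, test = holdout_half_split(y)
    np.testing.assert_array_equal(train, [0, 1, 4, 5])
    np.testing.assert_array_equal(test, [2, 3, 6, 7])


def test_holdout_half_separable_and_deterministic():
    rng = np.random.default_rng(7)
    X, y = gaussian_blobs(rng, [(-6.0,), (6.0,)], 100)
    order = np.argsort(y, kind="stable")
    fm = as_matrix(X[order], y[order])
    a = evaluate_holdout_half(fm)
    b = evaluate_holdout_half(fm)
    assert a.accuracy_pct >= 99.0
    assert a.accuracy_pct == b.accuracy_pct


def test_holdout_unseen_class_is_always_wrong():
    # class 1 has 2 windows: 1 trains, 1 tests; class 0 dominates.
    X = np.concatenate((np.zeros((10, 1)), np.full((2, 1), 100.0)))
    y = np.array([0] * 10 + [1] * 2)
    train, test = holdout_half_split(y)
    assert 10 in train and 11 in test


def test_holdout_singleton_class_rejected():
    y = np.array([0, 0, 1])
    with pytest.raises(ValueError, match="halve"):
        holdout_half_split(y)
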