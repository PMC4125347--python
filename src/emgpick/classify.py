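"""Movement classification and the two evaluation protocols.

Linear discriminant analysis (pooled-covariance, priors from training
counts) and k-nearest neighbours (Euclidean majority vote) wrap
scikit-learn estimators.  Accuracy is the percentage of correct
decisions over all decisions.

Two protocols:

``cv5``
    Seeded, class-stratified 5-fold cross-validation; the reported
    accuracy is the mean over the five folds.  Used with MCCSP- and
    FMS-selected channel subsets.
``holdout_half``
    Deterministic temporal split: within each class, the first half of
    its windows trains and the second half tests.  Used inside SFS,
    where cross-validating every greedy step would be circular and
    costly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureMatrix

DEFAULT_KNN_K = 5


@dataclass
class ClassificationResult:
    accuracy_pct: float
    per_fold: list[float] = field(default_factory=list)
    protocol: str = "holdout_half"
    classifier: str = "lda"
    feature_set: str = "td"

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "per_fold": self.per_fold,
            "protocol": self.protocol,
            "classifier": self.classifier,
            "feature_set": self.feature_set,
        }


def accuracy_pct(predicted: np.ndarray, true: np.ndarray) -> float:
    """100 * correct / total."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("prediction/label shape mismatch")
    return 100.0 * float(np.mean(predicted == true))


def lda_train(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Fit pooled-covariance LDA with empirical class priors.

    The SVD solver handles a singular pooled covariance by working in
    the span of the data, which plays the role of explicit ridge
    regularization for degenerate feature matrices.  With no residual
    degrees of freedom at all (one sample per class) the pooled
    covariance is undefined and the discriminant degenerates to a
    nearest-class-mean rule, which is what is fitted then.
    """
    labels = np.asarray(labels)
    n_classes = np.unique(labels).size
    if n_classes < 2:
        raise ValueError("LDA needs >= 2 classes in training data")
    if np.asarray(features).shape[0] <= n_classes:
        from sklearn.neighbors import NearestCentroid

        warnings.warn(
            "no residual degrees of freedom for a pooled covariance; "
            "fitting the nearest-class-mean limit of LDA",
            stacklevel=2,
        )
        model = NearestCentroid()
        model.fit(features, labels)
        return model
    model = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings on degenerate inputs
        model.fit(features, labels)
    return model


def lda_predict(model, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


def knn_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    k: int = DEFAULT_KNN_K,
) -> np.ndarray:
    """Euclidean k-NN majority vote; voting ties go to the smallest label."""
    n_train = np.asarray(train_features).shape[0]
    if k > n_train:
        raise ValueError(f"k={k} exceeds training size {n_train}")
    model = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    model.fit(train_features, train_labels)
    return model.predict(test_features)


def _predict(
    classifier: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    knn_k: int,
) -> np.ndarray:
    classifier = classifier.lower()
    if classifier == "lda":
        return lda_predict(lda_train(train_X, train_y), test_X)
    if classifier == "knn":
        return knn_predict(train_X, train_y, test_X, k=min(knn_k, train_X.shape[0]))
    raise ValueError(f"unknown classifier: {classifier!r}")


def evaluate_cv5(
    features: FeatureMatrix,
    classifier: str = "lda",
    seed: int = 0,
    knn_k: int = DEFAULT_KNN_K,
    n_folds: int = 5,
) -> ClassificationResult:
    """Seeded stratified 5-fold cross-validated accuracy.

    Windows are randomly partitioned into five near-equal folds,
    stratified by class; if some class has fewer windows than folds the
    split degrades to unstratified with a warning.  The accuracy is the
    mean of the five fold accuracies.
    """
    X, y = features.values, features.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"a class has only {counts.min()} windows; falling back to "
            "unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in splitter.split(X, y):
        pred = _predict(classifier, X[train_idx], y[train_idx], X[test_idx], knn_k)
        per_fold.append(accuracy_pct(pred, y[test_idx]))
    return ClassificationResult(
        accuracy_pct=float(np.mean(per_fold)),
        per_fold=per_fold,
        protocol="cv5",
        classifier=classifier,
        feature_set=features.feature_set,
    )


def holdout_half_split(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class temporal half split: first-half indices train, rest test.

    Rows of each class are split at their midpoint in row (temporal)
    order, the earlier ``ceil(n/2)`` rows training.  A purely positional
    split of the whole matrix could drop entire classes from one side
    when windows are grouped by class; splitting within class preserves
    the train-early/test-late intent for every class.
    """
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        if rows.size < 2:
            raise ValueError(f"class {c} has {rows.size} window(s); cannot halve")
        cut = (rows.size + 1) // 2
        train_idx.extend(rows[:cut])
        test_idx.extend(rows[cut:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def evaluate_holdout_half(
    features: FeatureMatrix,
    classifier: str = "lda",
    knn_k: int = DEFAULT_KNN_K,
) -> ClassificationResult:
    """Deterministic first-half-train / second-half-test accuracy."""
    X, y = features.values, features.labels
    train_idx, test_idx = holdout_half_split(y)
    pred = _predict(classifier, X[train_idx], y[train_idx], X[test_idx], knn_k)
    return ClassificationResult(
        accuracy_pct=accuracy_pct(pred, y[test_idx]),
        per_fold=[],
        protocol="holdout_half",
        classifier=classifier,
        feature_set=features.feature_set,
    )
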