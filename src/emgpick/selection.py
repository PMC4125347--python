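"""Channel-selection methods: multi-class CSP, SFS and Fisher-score ranking.

Three selectors with three different dependence structures:

MCCSP (multi-class common spatial patterns)
    Works directly on the raw multichannel signal — independent of any
    feature set or classifier.  For each class ``c`` a two-class CSP
    problem is solved between the class covariance ``S_c`` and the sum
    of all other classes' covariances (one-versus-rest).  CSP finds the
    spatial filter matrix ``W`` maximizing ``(w' S_c w)/(w' S_rest w)``,
    equivalently simultaneously diagonalizing both covariances with
    ``D_c + D_rest = I``.  The columns of ``W^{-1}`` (the spatial
    patterns) give each component's channel-space signature; the
    channels carrying the largest absolute coefficient of the first and
    last pattern are taken as that class's two most discriminative
    channels, and channels are ranked by how often they are picked
    across classes.

SFS (sequential forward selection)
    A wrapper method: greedily adds the channel that maximizes the
    classification accuracy of a chosen feature set + classifier,
    evaluated under a chosen protocol.  Selecting ``n`` of ``d``
    channels costs ``(2d + 1 - n) * n / 2`` classifier evaluations.

FMS (Fisher-score feature ranking)
    Ranks individual features by Fisher's class-separation criterion
    (between-class variance of the feature over pooled within-class
    variance) and maps feature ranks back to their channels.  This is
    the linear (Fisher-score) special case of the Fisher-Markov
    selector; the kernelized Markov-random-field formulation is out of
    scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg as sla

from .features import FEATURES_PER_CHANNEL, FeatureMatrix, build_feature_matrix
from .recording import EmgRecording

#: cap on the number of selected channels used throughout the reference protocol
DEFAULT_MAX_CHANNELS = 18


@dataclass
class SpatialFilterSet:
    """One class's CSP solution.

    ``filters`` holds the spatial filters as rows (``W``), scaled so that
    ``W (S_a + S_b) W' = I``; ``patterns`` is ``W^{-1}`` whose columns
    are the spatial patterns.  ``eig_target[i]`` is the fraction of the
    composite variance that component ``i`` explains for the target
    class, sorted descending, and ``eig_target + eig_other = 1``.
    """

    filters: np.ndarray
    patterns: np.ndarray
    eig_target: np.ndarray
    eig_other: np.ndarray
    class_label: int | None = None

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]


@dataclass
class ChannelRanking:
    """Ordered unique channel indices with per-channel scores.

    ``scores`` is non-increasing along the ranking: occurrence counts
    for MCCSP, best running accuracy for SFS, best Fisher feature score
    for FMS.
    """

    method: str
    ranked_channels: list[int]
    scores: list[float]
    n_evaluations: int | None = None

    def top(self, k: int) -> list[int]:
        if k > len(self.ranked_channels):
            raise ValueError(
                f"{self.method} ranking holds {len(self.ranked_channels)} "
                f"channels; cannot take top {k}"
            )
        return self.ranked_channels[:k]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ranked_channels": [int(c) for c in self.ranked_channels],
            "scores": [float(s) for s in self.scores],
        }


@dataclass
class FeatureRanking:
    """Feature indices ordered by descending Fisher score."""

    ranked_features: list[int]
    scores: list[float]


def n_channel_combinations(d: int, n: int) -> int:
    """Number of distinct n-channel subsets of d channels (C(d, n)).

    The size of the search space an exhaustive selector would face —
    32,468,436 for 6 of 56 channels — which is why greedy and
    eigenstructure-based selectors are used instead.
    """
    return math.comb(d, n)


# ---------------------------------------------------------------------------
# covariances and CSP


def class_covariance(recording: EmgRecording, class_label: int) -> np.ndarray:
    """Channel covariance of one class, pooled over its trials.

    Samples of the class are mean-centered per channel and the
    ``d x d`` sample covariance (normalized by ``n - 1``) is returned.
    """
    X = recording.class_samples(class_label)
    if X.shape[0] < 2:
        raise ValueError(
            f"class {class_label} has {X.shape[0]} sample(s); covariance undefined"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    return (Xc.T @ Xc) / (X.shape[0] - 1)


def csp(
    sigma_a: np.ndarray, sigma_b: np.ndarray, ridge: float = 1e-8
) -> SpatialFilterSet:
    """Two-class common spatial patterns from a covariance pair.

    Solves the generalized eigenproblem ``S_a w = lam (S_a + S_b) w``.
    If the composite ``S_a + S_b`` is numerically singular, a diagonal
    ridge of ``ridge * (trace/d)`` is added to each covariance first;
    well-conditioned inputs are solved unperturbed so the returned
    filters diagonalize the covariances exactly (to solver precision).
    Eigenvectors are scaled so that ``W (S_a + S_b) W' = I``;
    components are sorted by descending target-class eigenvalue.
    """
    sigma_a = np.asarray(sigma_a, dtype=np.float64)
    sigma_b = np.asarray(sigma_b, dtype=np.float64)
    if sigma_a.shape != sigma_b.shape or sigma_a.ndim != 2:
        raise ValueError(
            f"covariance shapes differ: {sigma_a.shape} vs {sigma_b.shape}"
        )
    d = sigma_a.shape[0]
    if sigma_a.shape[1] != d:
        raise ValueError("covariances must be square")
    sa, sb = sigma_a, sigma_b
    comp_eigs = np.linalg.eigvalsh(sa + sb)
    if comp_eigs[0] <= 1e-10 * max(comp_eigs[-1], np.finfo(float).tiny):
        sa = sigma_a + ridge * (np.trace(sigma_a) / d) * np.eye(d)
        sb = sigma_b + ridge * (np.trace(sigma_b) / d) * np.eye(d)
    composite = sa + sb
    try:
        lam, V = sla.eigh(sa, composite)  # ascending; V' composite V = I
    except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "composite covariance numerically singular after ridge; "
            "increase the ridge or check the input covariances"
        ) from exc
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    W = V[:, order].T
    patterns = np.linalg.inv(W)
    return SpatialFilterSet(
        filters=W,
        patterns=patterns,
        eig_target=lam,
        eig_other=1.0 - lam,
    )


def mccsp(
    recording: EmgRecording,
    classes: Sequence[int] | None = None,
    ridge: float = 1e-8,
) -> list[SpatialFilterSet]:
    """One-versus-rest CSP: one filter set per class, ordered by label.

    For class ``c`` the target covariance is ``S_c`` and the "rest"
    covariance is the element-wise sum of all other classes'
    covariances.  With two classes this reduces exactly to the
    two-class problems ``csp(S_a, S_b)`` and ``csp(S_b, S_a)``.
    """
    if classes is None:
        classes = [int(c) for c in recording.classes]
    else:
        classes = [int(c) for c in classes]
    if len(classes) < 2:
        raise ValueError(f"one-versus-rest needs >= 2 classes, got {len(classes)}")
    covs = {c: class_covariance(recording, c) for c in classes}
    out = []
    for c in classes:
        rest = sum(covs[i] for i in classes if i != c)
        fs = csp(covs[c], rest, ridge=ridge)
        fs.class_label = c
        out.append(fs)
    return out


def pick_channels_from_pattern(filter_set: SpatialFilterSet) -> tuple[int, int]:
    """Channels carrying the first and last spatial patterns.

    Returns the row index of the maximal absolute coefficient of the
    first and of the last pattern column (pattern sign is arbitrary up
    to eigenvector sign, so magnitudes are compared); ties go to the
    lowest channel index.
    """
    P = filter_set.patterns
    ch_first = int(np.argmax(np.abs(P[:, 0])))
    ch_last = int(np.argmax(np.abs(P[:, -1])))
    return ch_first, ch_last


def mccsp_rank_channels(
    recording: EmgRecording,
    max_channels: int = DEFAULT_MAX_CHANNELS,
    classes: Sequence[int] | None = None,
    ridge: float = 1e-8,
) -> ChannelRanking:
    """Rank channels by how often the per-class CSP patterns pick them.

    Each class contributes two picks (first and last pattern); channels
    are ranked by descending occurrence count, ties broken by lowest
    channel index.  At most ``max_channels`` channels are returned; the
    ranking is fully deterministic given the recording.
    """
    counts: dict[int, int] = {}
    for fs in mccsp(recording, classes=classes, ridge=ridge):
        for ch in pick_channels_from_pattern(fs):
            counts[ch] = counts.get(ch, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_channels]
    return ChannelRanking(
        method="MCCSP",
        ranked_channels=[c for c, _ in ordered],
        scores=[float(n) for _, n in ordered],
    )


# ---------------------------------------------------------------------------
# sequential forward selection


def sfs_evaluation_count(d: int, n: int) -> int:
    """Classifier evaluations needed to pick n of d channels greedily."""
    return (2 * d + 1 - n) * n // 2


def sfs_select(
    recording: EmgRecording,
    candidate_channels: Sequence[int] | None = None,
    n_target: int | None = None,
    feature_set: str = "td",
    classifier: str = "lda",
    eval_protocol: str = "holdout_half",
    seed: int = 0,
    win_ms: float = 150.0,
    step_ms: float = 100.0,
    accuracy_fn: Callable[[FeatureMatrix], float] | None = None,
) -> ChannelRanking:
    """Greedy forward channel selection by classification accuracy.

    At each step every remaining candidate is appended in turn to the
    current set, the accuracy of the resulting feature matrix is
    evaluated (half/half temporal holdout by default, or 5-fold CV),
    and the argmax is kept; accuracy ties go to the lowest channel
    index.  Channels are returned in selection order with the accuracy
    achieved when each was added; ``n_evaluations`` records the number
    of classifier evaluations, ``(2d + 1 - n) * n / 2`` for ``d``
    candidates.

    ``accuracy_fn`` overrides the built-in evaluation (useful for cheap
    surrogate scorers); it receives the candidate feature matrix and
    returns a score to maximize.
    """
    from .classify import evaluate_cv5, evaluate_holdout_half

    if candidate_channels is None:
        candidate_channels = range(recording.n_channels)
    candidates = [int(c) for c in candidate_channels]
    if n_target is None:
        n_target = len(candidates)
    if not 1 <= n_target <= len(candidates):
        raise ValueError(
            f"n_target={n_target} outside [1, {len(candidates)}] candidates"
        )

    # one feature pass over all candidates; subsets are column slices
    full = build_feature_matrix(
        recording, candidates, feature_set=feature_set, win_ms=win_ms, step_ms=step_ms
    )

    if accuracy_fn is None:
        if eval_protocol == "holdout_half":
            accuracy_fn = lambda fm: evaluate_holdout_half(
                fm, classifier=classifier
            ).accuracy_pct
        elif eval_protocol == "cv5":
            accuracy_fn = lambda fm: evaluate_cv5(
                fm, classifier=classifier, seed=seed
            ).accuracy_pct
        else:
            raise ValueError(f"unknown eval protocol: {eval_protocol!r}")

    selected: list[int] = []
    step_scores: list[float] = []
    remaining = list(candidates)
    n_evaluations = 0
    while len(selected) < n_target:
        best_ch, best_acc = None, -np.inf
        for ch in remaining:  # candidates in listed (ascending-index) order
            acc = accuracy_fn(full.select_channels(selected + [ch]))
            n_evaluations += 1
            if acc > best_acc:
                best_ch, best_acc = ch, acc
        selected.append(best_ch)
        step_scores.append(float(best_acc))
        remaining.remove(best_ch)
    return ChannelRanking(
        method="SFS",
        ranked_channels=selected,
        scores=step_scores,
        n_evaluations=n_evaluations,
    )


# ---------------------------------------------------------------------------
# Fisher-score feature ranking


def fms_rank(features: FeatureMatrix) -> FeatureRanking:
    """Rank features by Fisher's class-separation score.

    ``S_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c var_cj`` with class
    means ``mu_cj``, overall mean ``mu_j`` and within-class variances
    ``var_cj``.  A feature whose within-class variance vanishes in every
    class while its class means differ is perfectly separating; its
    score is infinite and it ranks first.  Ties go to the lower feature
    index.
    """
    X, y = features.values, features.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Fisher score needs >= 2 classes")
    if X.shape[1] < 2:
        raise ValueError("Fisher score needs >= 2 features")
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        n_c = Xc.shape[0]
        between += n_c * (Xc.mean(axis=0) - mu) ** 2
        within += n_c * Xc.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = between / within
    score[np.isnan(score)] = 0.0  # 0/0: constant feature, no separation
    order = np.lexsort((np.arange(score.size), -score))
    return FeatureRanking(
        ranked_features=[int(j) for j in order],
        scores=[float(score[j]) for j in order],
    )


def map_feature_rank_to_channels(
    feature_rank: Sequence[int],
    features_per_channel: int,
    scores: Sequence[float] | None = None,
) -> ChannelRanking:
    """Collapse a feature ranking to a channel ranking.

    The channel of feature ``j`` is ``j // features_per_channel`` under
    the channel-block column layout; duplicate channels keep their
    first (best-ranked) occurrence.  Channel scores, if feature scores
    are given, are each channel's best feature score.
    """
    channels: list[int] = []
    ch_scores: list[float] = []
    seen: set[int] = set()
    for pos, j in enumerate(feature_rank):
        ch = int(j) // features_per_channel
        if ch not in seen:
            seen.add(ch)
            channels.append(ch)
            ch_scores.append(float(scores[pos]) if scores is not None else float(-pos))
    return ChannelRanking(method="FMS", ranked_channels=channels, scores=ch_scores)


def fms_rank_channels(features: FeatureMatrix) -> ChannelRanking:
    """Fisher-score channel ranking of a feature matrix.

    Note the result depends on the feature set used to build
    ``features`` (unlike MCCSP); the returned channel ids are the global
    ids carried by the feature matrix.
    """
    fr = fms_rank(features)
    fpc = features.features_per_channel
    local = map_feature_rank_to_channels(fr.ranked_features, fpc, scores=fr.scores)
    return ChannelRanking(
        method="FMS",
        ranked_channels=[int(features.channel_ids[c]) for c in local.ranked_channels],
        scores=local.scores,
    )
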