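"""CSP/MCCSP channel selection and the SFS/FMS baselines."""

import numpy as np
import pytest

from emgpick import (
    FeatureMatrix,
    build_feature_matrix,
    class_covariance,
    csp,
    evaluate_holdout_half,
    fms_rank,
    fms_rank_channels,
    map_feature_rank_to_channels,
    mccsp,
    mccsp_rank_channels,
    pick_channels_from_pattern,
    sfs_evaluation_count,
    sfs_select,
)
from emgpick.synth import SynthConfig, generate_recording
from tests.conftest import make_recording


def random_spd(rng, d):
    A = rng.standard_normal((d, d))
    return A @ A.T + d * np.eye(d) * 0.1


def oracle_eigvals(sa, sb):
    """Independent route: plain eigendecomposition of inv(Sa+Sb) @ Sa."""
    lam = np.linalg.eigvals(np.linalg.solve(sa + sb, sa))
    return np.sort(lam.real)[::-1]


# ---------------------------------------------------------------------------
# covariance


def test_class_covariance_identity_for_unit_noise():
    rng = np.random.default_rng(0)
    rec = make_recording(rng.standard_normal((40_000, 5)))
    cov = class_covariance(rec, 0)
    np.testing.assert_allclose(cov, np.eye(5), atol=0.05)


def test_class_covariance_symmetric_psd(small_rec):
    cov = class_covariance(small_rec, 1)
    np.testing.assert_allclose(cov, cov.T, atol=1e-12)
    assert np.linalg.eigvalsh(cov).min() >= -1e-10


def test_class_covariance_single_sample_rejected():
    rec = make_recording(np.zeros((3, 2)), labels=np.array([0, 0, 1]))
    with pytest.raises(ValueError, match="covariance undefined"):
        class_covariance(rec, 1)
    with pytest.raises(ValueError, match="unknown class"):
        class_covariance(rec, 9)


# ---------------------------------------------------------------------------
# CSP core


def test_csp_equal_covariances_give_half_eigenvalues():
    rng = np.random.default_rng(1)
    S = random_spd(rng, 6)
    fs = csp(S, S)
    np.testing.assert_allclose(fs.eig_target, 0.5, atol=1e-10)


def test_csp_diagonal_closed_form():
    fs = csp(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]))
    np.testing.assert_allclose(fs.eig_target, [2 / 3, 1 / 3], atol=1e-10)
    # axis-aligned patterns: first pattern on channel 0, last on channel 1
    assert pick_channels_from_pattern(fs) == (0, 1)


@pytest.mark.parametrize("d", [2, 5, 10, 20])
def test_csp_invariants_on_random_spd_pairs(d):
    rng = np.random.default_rng(d)
    for _ in range(25):
        sa, sb = random_spd(rng, d), random_spd(rng, d)
        fs = csp(sa, sb)
        WA = fs.filters @ sa @ fs.filters.T
        WB = fs.filters @ sb @ fs.filters.T
        scale = max(np.abs(WA).max(), np.abs(WB).max())
        assert np.abs(WA - np.diag(np.diag(WA))).max() <= 1e-8 * scale
        assert np.abs(WB - np.diag(np.diag(WB))).max() <= 1e-8 * scale
        np.testing.assert_allclose(fs.eig_target + fs.eig_other, 1.0, atol=1e-8)
        np.testing.assert_allclose(
            fs.patterns @ fs.filters, np.eye(d), atol=1e-8
        )
        assert np.all(np.diff(fs.eig_target) <= 1e-12)
        np.testing.assert_allclose(
            fs.eig_target, oracle_eigvals(sa, sb), atol=1e-8
        )


def test_csp_argument_swap_reverses_spectrum():
    rng = np.random.default_rng(5)
    sa, sb = random_spd(rng, 7), random_spd(rng, 7)
    ab = csp(sa, sb)
    ba = csp(sb, sa)
    np.testing.assert_allclose(ab.eig_target, (1 - ba.eig_target)[::-1], atol=1e-8)


def test_csp_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        csp(np.eye(3), np.eye(4))


# ---------------------------------------------------------------------------
# multi-class extension


def test_mccsp_two_classes_reduces_to_pairwise_csp(small_rec):
    rec = small_rec
    two = [int(c) for c in rec.classes[:2]]
    sa = class_covariance(rec, two[0])
    sb = class_covariance(rec, two[1])
    out = mccsp(rec, classes=two)
    np.testing.assert_allclose(out[0].eig_target, csp(sa, sb).eig_target, atol=1e-10)
    np.testing.assert_allclose(out[1].eig_target, csp(sb, sa).eig_target, atol=1e-10)


def test_mccsp_identical_classes_give_one_over_c():
    cfg = SynthConfig(n_classes=3, n_channels=6, trial_s=4.0, n_trials=2, seed=9)
    rec, _ = generate_recording(cfg)  # no planted structure
    for fs in mccsp(rec):
        np.testing.assert_allclose(fs.eig_target, 1 / 3, atol=0.05)


def test_mccsp_single_class_rejected():
    rec = make_recording(np.random.default_rng(0).standard_normal((100, 3)))
    with pytest.raises(ValueError, match="2 classes"):
        mccsp(rec)


def test_first_pattern_recovers_planted_channel():
    imap = {c: frozenset({2 * c}) for c in range(6)}
    hits = total = 0
    for seed in range(10):
        cfg = SynthConfig(
            n_classes=6, n_channels=12, trial_s=2.0, n_trials=3, gain=3.0,
            informative_map=imap, seed=seed,
        )
        rec, _ = generate_recording(cfg)
        for fs in mccsp(rec):
            ch_first, _ = pick_channels_from_pattern(fs)
            hits += ch_first == 2 * fs.class_label
            total += 1
    assert hits / total >= 0.95


def test_pick_channels_identity_and_sign_conventions():
    fs = csp(np.diag([3.0, 2.0, 1.0]), np.diag([1.0, 2.0, 3.0]))
    fs.patterns = np.eye(3)
    assert pick_channels_from_pattern(fs) == (0, 2)
    fs.patterns = np.array(
        [[0.1, 0.0, 1.0], [-0.9, 1.0, 0.0], [0.2, 0.0, 0.0]]
    )
    assert pick_channels_from_pattern(fs)[0] == 1  # |-0.9| wins


def test_mccsp_ranking_deterministic_and_bounded(rec_4x2):
    rec, imap = rec_4x2
    r1 = mccsp_rank_channels(rec)
    r2 = mccsp_rank_channels(rec)
    assert r1.ranked_channels == r2.ranked_channels
    assert r1.scores == r2.scores
    assert len(r1.ranked_channels) <= 2 * len(rec.classes)
    assert all(a >= b for a, b in zip(r1.scores, r1.scores[1:]))
    # every pick lands on a planted channel in this high-contrast regime
    planted = set().union(*imap.values())
    assert set(r1.ranked_channels) <= planted


def test_mccsp_ranking_invariant_to_uniform_rescaling(rec_4x2):
    rec, _ = rec_4x2
    r1 = mccsp_rank_channels(rec)
    r2 = mccsp_rank_channels(rec.with_signal(3.7 * rec.signal))
    assert r1.ranked_channels == r2.ranked_channels
    # per-channel rescaling changes the covariances and MAY change the
    # ranking; it must still run deterministically
    gains = np.linspace(0.5, 2.0, rec.n_channels)
    r3 = mccsp_rank_channels(rec.with_signal(rec.signal * gains))
    assert len(r3.ranked_channels) > 0


# ---------------------------------------------------------------------------
# SFS


def test_sfs_budget_formula():
    assert sfs_evaluation_count(56, 6) == 321
    for d in (8, 20, 56):
        for n in (1, 3, 6):
            assert sfs_evaluation_count(d, n) == (2 * d + 1 - n) * n // 2


def test_sfs_first_pick_equals_exhaustive_single_channel_search():
    imap = {0: frozenset(), 1: frozenset({1}), 2: frozenset({4})}
    for seed in range(5):
        cfg = SynthConfig(
            n_classes=3, n_channels=6, trial_s=2.0, n_trials=2, gain=3.0,
            informative_map=imap, seed=seed,
        )
        rec, _ = generate_recording(cfg)
        r = sfs_select(rec, n_target=1)
        # brute-force oracle over every single channel
        best, best_acc = None, -np.inf
        for ch in range(rec.n_channels):
            fm = build_feature_matrix(rec, [ch], feature_set="td")
            acc = evaluate_holdout_half(fm, classifier="lda").accuracy_pct
            if acc > best_acc:
                best, best_acc = ch, acc
        assert r.ranked_channels == [best]
        assert r.scores[0] == pytest.approx(best_acc)


def test_sfs_selects_planted_channel_first():
    imap = {1: frozenset({3})}
    hits = 0
    for seed in range(10):
        cfg = SynthConfig(
            n_classes=2, n_channels=8, trial_s=2.0, n_trials=2, gain=4.0,
            informative_map=imap, seed=seed,
        )
        rec, _ = generate_recording(cfg)
        hits += sfs_select(rec, n_target=1).ranked_channels == [3]
    assert hits >= 9


def test_sfs_full_depth_returns_permutation(small_rec):
    r = sfs_select(small_rec, candidate_channels=range(5), n_target=5)
    assert sorted(r.ranked_channels) == list(range(5))
    assert r.n_evaluations == sfs_evaluation_count(5, 5)


def test_sfs_target_guard(small_rec):
    with pytest.raises(ValueError, match="n_target"):
        sfs_select(small_rec, candidate_channels=range(4), n_target=5)


# ---------------------------------------------------------------------------
# FMS


def _matrix(values, labels):
    values = np.asarray(values, float)
    n_ch = values.shape[1] // 4
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels),
        channel_ids=tuple(range(max(n_ch, 1))),
        feature_set="td",
    )


def test_fisher_score_zero_for_constant_feature():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((100, 2))
    X[:, 0] = 5.0
    fr = fms_rank(_matrix(X, np.repeat([0, 1], 50)))
    assert fr.scores[fr.ranked_features.index(0)] == 0.0


def test_fisher_score_separated_gaussians_dominate_noise():
    rng = np.random.default_rng(1)
    y = np.repeat([0, 1], 200)
    X = rng.standard_normal((400, 2))
    X[:, 0] += 10.0 * y  # means 0 and 10, sd 1
    fr = fms_rank(_matrix(X, y))
    assert fr.ranked_features[0] == 0
    scores = dict(zip(fr.ranked_features, fr.scores))
    assert scores[0] >= 20 * max(scores[1], 1e-12)


def test_fisher_score_collapses_under_label_permutation():
    rng = np.random.default_rng(2)
    y = np.repeat([0, 1], 200)
    X = rng.standard_normal((400, 2))
    X[:, 0] += 10.0 * y
    ref = fms_rank(_matrix(X, y)).scores[0]
    perm_scores = []
    for _ in range(20):
        yp = rng.permutation(y)
        fr = fms_rank(_matrix(X, yp))
        perm_scores.append(dict(zip(fr.ranked_features, fr.scores))[0])
    assert np.median(perm_scores) <= 0.10 * ref


def test_fisher_zero_within_class_variance_ranks_first():
    y = np.repeat([0, 1], 10)
    X = np.column_stack((np.repeat([0.0, 1.0], 10), np.random.default_rng(3).standard_normal(20)))
    fr = fms_rank(_matrix(X, y))
    assert fr.ranked_features[0] == 0
    assert np.isinf(fr.scores[0])


@pytest.mark.parametrize(
    "rank, fpc, expected",
    [
        ([0, 7, 1], 4, [0, 1]),
        ([4, 0], 4, [1, 0]),
        ([0, 1, 2, 3], 4, [0]),
    ],
)
def test_feature_to_channel_mapping(rank, fpc, expected):
    r = map_feature_rank_to_channels(rank, fpc)
    assert r.ranked_channels == expected


def test_fms_channel_ranking_finds_planted_channels(rec_8x1):
    rec, imap = rec_8x1
    fm = build_feature_matrix(rec, range(rec.n_channels), feature_set="td")
    r = fms_rank_channels(fm)
    planted = set().union(*imap.values())
    assert set(r.ranked_channels[:8]) == planted


# ---------------------------------------------------------------------------
# cross-method end-to-end recovery


def test_selected_channels_beat_random_channels(rec_4x2):
    from emgpick import evaluate_cv5

    rec, imap = rec_4x2
    full = build_feature_matrix(rec, range(rec.n_channels), feature_set="td")

    def acc(channels, seed):
        return evaluate_cv5(
            full.select_channels(channels), classifier="lda", seed=seed
        ).accuracy_pct

    mccsp_r = mccsp_rank_channels(rec)
    fms_r = fms_rank_channels(full)
    sfs_r = sfs_select(rec, n_target=8)
    rng = np.random.default_rng(0)
    wins = {"MCCSP": 0, "FMS": 0, "SFS": 0}
    n_seeds = 12
    for seed in range(n_seeds):
        rand_acc = acc(list(rng.choice(rec.n_channels, size=8, replace=False)), seed)
        k = min(8, len(mccsp_r.ranked_channels))
        wins["MCCSP"] += acc(mccsp_r.ranked_channels[:k], seed) >= rand_acc
        wins["FMS"] += acc(fms_r.ranked_channels[:8], seed) >= rand_acc
        wins["SFS"] += acc(sfs_r.ranked_channels[:8], seed) >= rand_acc
    for method, w in wins.items():
        assert w >= n_seeds - 2, f"{method} beat random in only {w}/{n_seeds} seeds"
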