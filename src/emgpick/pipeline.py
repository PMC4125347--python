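"""End-to-end experiment orchestration.

Reproduces the accuracy-versus-channel-count experiment: for each
selection method, obtain a channel ranking, then sweep the number of
retained channels ``k`` and evaluate every feature-set x classifier
combination on the top-``k`` channels.  MCCSP and FMS subsets are
scored with stratified 5-fold cross-validation; SFS subsets with the
deterministic half/half temporal holdout (the greedy search already
optimizes holdout accuracy, so cross-validating it again would be both
circular and costly).

The report half mirrors the channel-distribution comparison: which
channels each method selects under each feature-classifier
combination, and whether that set is fixed across combinations.  For
MCCSP it always is — the ranking never consults features or
classifiers; for SFS and FMS it generally is not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import evaluate_cv5, evaluate_holdout_half
from .features import build_feature_matrix
from .io import read_recording
from .montage import ElectrodeLayout, apply_bipolar_montage, build_bipolar_pairs
from .preprocess import highpass, notch50
from .recording import EmgRecording
from .selection import (
    ChannelRanking,
    fms_rank_channels,
    mccsp_rank_channels,
    sfs_select,
)
from .synth import SynthConfig, generate_recording

logger = logging.getLogger("emgpick")

DEFAULT_PROTOCOLS = {"MCCSP": "cv5", "FMS": "cv5", "SFS": "holdout_half"}


@dataclass
class ExperimentConfig:
    """One full sweep: montage x methods x feature sets x classifiers x k."""

    montage: str = "monopolar"
    methods: tuple[str, ...] = ("MCCSP", "SFS", "FMS")
    feature_sets: tuple[str, ...] = ("td", "tdar")
    classifiers: tuple[str, ...] = ("lda", "knn")
    k_range: tuple[int, ...] = tuple(range(1, 19))
    seed: int = 0
    input_path: str | None = None
    synth: SynthConfig | None = None
    layout: ElectrodeLayout = field(default_factory=ElectrodeLayout)
    apply_preprocessing: bool = True
    max_channels: int = 18
    sfs_max_k: int | None = 8
    knn_k: int = 5
    protocols: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PROTOCOLS))

    def __post_init__(self) -> None:
        self.methods = tuple(m.upper() for m in self.methods)
        self.feature_sets = tuple(f.lower() for f in self.feature_sets)
        self.classifiers = tuple(c.lower() for c in self.classifiers)
        if not (self.methods and self.feature_sets and self.classifiers):
            raise ValueError("methods, feature_sets and classifiers must be non-empty")
        for m in self.methods:
            if m not in ("MCCSP", "SFS", "FMS"):
                raise ValueError(f"unknown selection method: {m}")
        if not self.k_range or min(self.k_range) < 1:
            raise ValueError("k_range must contain positive channel counts")
        if self.input_path is None and self.synth is None:
            raise ValueError("config needs an input path or a synthesis config")


def _prepare_recording(config: ExperimentConfig) -> EmgRecording:
    if config.input_path is not None:
        rec = read_recording(config.input_path)
    else:
        rec, _ = generate_recording(config.synth)
    if config.montage == "bipolar":
        rec = apply_bipolar_montage(rec, build_bipolar_pairs(config.layout))
    elif config.montage != "monopolar":
        raise ValueError(f"unknown montage: {config.montage!r}")
    if config.apply_preprocessing:
        rec = notch50(highpass(rec))
    return rec


def compute_rankings(
    config: ExperimentConfig, recording: EmgRecording | None = None
) -> dict[tuple[str, str, str], ChannelRanking]:
    """Channel ranking per (method, feature_set, classifier) combination.

    MCCSP is computed once and shared across combinations; FMS depends
    on the feature set only; SFS depends on both feature set and
    classifier.
    """
    rec = recording if recording is not None else _prepare_recording(config)
    d = rec.n_channels
    if max(config.k_range) > d:
        raise ValueError(
            f"k_range max {max(config.k_range)} exceeds {d} available channels"
        )
    rankings: dict[tuple[str, str, str], ChannelRanking] = {}
    if "MCCSP" in config.methods:
        r = mccsp_rank_channels(rec, max_channels=config.max_channels)
        logger.info("MCCSP ranked %d channels: %s", len(r.ranked_channels), r.ranked_channels)
        for fs in config.feature_sets:
            for clf in config.classifiers:
                rankings[("MCCSP", fs, clf)] = r
    if "FMS" in config.methods:
        for fs in config.feature_sets:
            fm = build_feature_matrix(rec, range(d), feature_set=fs)
            r = fms_rank_channels(fm)
            logger.info("FMS(%s) top channels: %s", fs, r.ranked_channels[:10])
            for clf in config.classifiers:
                rankings[("FMS", fs, clf)] = r
    if "SFS" in config.methods:
        n_target = max(config.k_range)
        if config.sfs_max_k is not None and n_target > config.sfs_max_k:
            warnings.warn(
                f"SFS capped at k={config.sfs_max_k} (requested {n_target}); "
                "raise sfs_max_k to search further",
                stacklevel=2,
            )
            n_target = config.sfs_max_k
        for fs in config.feature_sets:
            for clf in config.classifiers:
                r = sfs_select(
                    rec,
                    candidate_channels=range(d),
                    n_target=min(n_target, d),
                    feature_set=fs,
                    classifier=clf,
                    eval_protocol=config.protocols.get("SFS", "holdout_half"),
                    seed=config.seed,
                )
                logger.info(
                    "SFS(%s,%s) selected %s in %d evaluations",
                    fs, clf, r.ranked_channels, r.n_evaluations,
                )
                rankings[("SFS", fs, clf)] = r
    return rankings


def run_channel_curve(
    config: ExperimentConfig,
    recording: EmgRecording | None = None,
    rankings: Mapping[tuple[str, str, str], ChannelRanking] | None = None,
) -> pd.DataFrame:
    """Accuracy-versus-channel-count table for every configured combination.

    Returns one row per (method, feature_set, classifier, k).  A ``k``
    beyond a method's ranking length (MCCSP rankings hold at most two
    channels per class; SFS may be capped) yields an ``accuracy_pct``
    of NaN so the sweep cardinality is preserved.
    """
    rec = recording if recording is not None else _prepare_recording(config)
    if rankings is None:
        rankings = compute_rankings(config, recording=rec)
    # one feature pass per feature set; every (method, k) reuses column subsets
    full = {
        fs: build_feature_matrix(rec, range(rec.n_channels), feature_set=fs)
        for fs in config.feature_sets
    }
    rows = []
    for method in config.methods:
        protocol = config.protocols.get(method, DEFAULT_PROTOCOLS[method])
        for fs in config.feature_sets:
            for clf in config.classifiers:
                ranking = rankings[(method, fs, clf)]
                for k in config.k_range:
                    if k > len(ranking.ranked_channels):
                        acc = float("nan")
                    else:
                        sub = full[fs].select_channels(ranking.top(k))
                        if protocol == "cv5":
                            res = evaluate_cv5(
                                sub, classifier=clf, seed=config.seed,
                                knn_k=config.knn_k,
                            )
                        else:
                            res = evaluate_holdout_half(
                                sub, classifier=clf, knn_k=config.knn_k
                            )
                        acc = res.accuracy_pct
                        logger.debug(
                            "eval method=%s fs=%s clf=%s k=%d acc=%.2f",
                            method, fs, clf, k, acc,
                        )
                    rows.append(
                        {
                            "method": method,
                            "montage": config.montage,
                            "feature_set": fs,
                            "classifier": clf,
                            "k": k,
                            "accuracy_pct": acc,
                        }
                    )
    return pd.DataFrame(rows)


def channel_distribution_report(
    rankings: Mapping[tuple[str, str, str], ChannelRanking],
    k: int | None = None,
) -> dict[str, dict]:
    """Per-method map of selected channels per feature-classifier combination.

    ``k`` truncates every ranking to its top-``k`` (default: full
    ranking).  Each method's entry carries the channel set per
    combination and a ``fixed_across_combinations`` flag — true iff all
    combinations select the same set.
    """
    report: dict[str, dict] = {}
    for (method, fs, clf), ranking in rankings.items():
        chans = ranking.ranked_channels
        if k is not None:
            chans = chans[: min(k, len(chans))]
        entry = report.setdefault(method, {"combinations": {}})
        entry["combinations"][f"{fs}-{clf}"] = sorted(int(c) for c in chans)
    for method, entry in report.items():
        sets = [tuple(v) for v in entry["combinations"].values()]
        entry["fixed_across_combinations"] = len(set(sets)) == 1
    return report
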