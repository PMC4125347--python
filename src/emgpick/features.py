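"""Analysis-window segmentation and time-domain EMG feature sets.

Two classic feature sets are provided, extracted per channel from
sliding analysis windows (default 150 ms length, 100 ms increment):

TD
    The Hudgins time-domain set — mean absolute value (MAV), zero
    crossings (ZC), slope sign changes (SSC), waveform length (WL);
    4 features per channel.
TDAR
    Six autoregressive model coefficients (Burg estimate, prediction
    convention ``x_t = sum_i a_i x_{t-i} + e_t``) plus the root mean
    square amplitude; 7 features per channel.

Windows never span a trial boundary and inherit their trial's class
label.  Feature-matrix columns are laid out channel-block-major:
all features of ``channel_ids[0]``, then ``channel_ids[1]``, ...
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from statsmodels.regression.linear_model import burg as _burg

from .recording import EmgRecording

TD_FEATURE_NAMES = ("mav", "zc", "ssc", "wl")
AR_ORDER = 6
TDAR_FEATURE_NAMES = tuple(f"ar{i}" for i in range(1, AR_ORDER + 1)) + ("rms",)

FEATURES_PER_CHANNEL = {"td": len(TD_FEATURE_NAMES), "tdar": len(TDAR_FEATURE_NAMES)}


@dataclass(frozen=True)
class Window:
    """Half-open sample range of one analysis window plus its annotations."""

    start: int
    stop: int
    label: int
    trial_id: int


@dataclass
class FeatureMatrix:
    """Windows x (channels x features-per-channel) feature matrix."""

    values: np.ndarray
    labels: np.ndarray
    channel_ids: tuple[int, ...]
    feature_set: str

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def features_per_channel(self) -> int:
        return FEATURES_PER_CHANNEL[self.feature_set]

    @property
    def column_names(self) -> list[str]:
        names = TD_FEATURE_NAMES if self.feature_set == "td" else TDAR_FEATURE_NAMES
        return [f"ch{c}_{f}" for c in self.channel_ids for f in names]

    def select_channels(self, channel_ids) -> "FeatureMatrix":
        """Column-subset view restricted to ``channel_ids`` (kept in given order)."""
        fpc = self.features_per_channel
        pos = {c: i for i, c in enumerate(self.channel_ids)}
        cols = []
        for c in channel_ids:
            if c not in pos:
                raise ValueError(f"channel {c} not present in this feature matrix")
            cols.extend(range(pos[c] * fpc, (pos[c] + 1) * fpc))
        return FeatureMatrix(
            values=self.values[:, cols],
            labels=self.labels,
            channel_ids=tuple(int(c) for c in channel_ids),
            feature_set=self.feature_set,
        )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.column_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    def to_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            values=self.values,
            labels=self.labels,
            channel_ids=np.asarray(self.channel_ids),
            feature_set=np.str_(self.feature_set),
        )


def segment_windows(
    recording: EmgRecording, win_ms: float = 150.0, step_ms: float = 100.0
) -> list[Window]:
    """Slide analysis windows over each trial segment.

    Window length ``L = floor(win_ms * fs / 1000)`` samples, stride
    ``S = floor(step_ms * fs / 1000)``; a trial shorter than ``L``
    contributes no windows.
    """
    L = int(win_ms * recording.fs / 1000.0)
    S = int(step_ms * recording.fs / 1000.0)
    if L < 3 or S < 1:
        raise ValueError(f"degenerate window parameters: L={L}, S={S}")
    windows: list[Window] = []
    for seg in recording.trial_segments():
        n = seg.n_samples
        if n < L:
            continue
        for k in range((n - L) // S + 1):
            a = seg.start + k * S
            windows.append(Window(a, a + L, seg.label, seg.trial_id))
    return windows


def window_lengths(fs: float, win_ms: float = 150.0, step_ms: float = 100.0):
    """(L, S): window length and stride in samples."""
    return int(win_ms * fs / 1000.0), int(step_ms * fs / 1000.0)


# ---------------------------------------------------------------------------
# single-window feature primitives


def td_features(window: np.ndarray, deadband: float = 0.0):
    """Hudgins time-domain features of one single-channel window.

    Returns ``(MAV, ZC, SSC, WL)`` where ZC counts sign changes between
    consecutive samples whose difference exceeds ``deadband`` in
    magnitude, and SSC counts interior samples whose two adjacent first
    differences have opposite signs with at least one exceeding
    ``deadband``.
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    if x.size < 3:
        raise ValueError(f"window of {x.size} samples too short for TD features")
    m = _td_block(x[None, :], deadband)
    return float(m[0, 0]), float(m[0, 1]), float(m[0, 2]), float(m[0, 3])


def _td_block(X: np.ndarray, deadband: float) -> np.ndarray:
    """Vectorized TD features; X is (n_windows, L) -> (n_windows, 4)."""
    d = np.diff(X, axis=1)
    mav = np.abs(X).mean(axis=1)
    wl = np.abs(d).sum(axis=1)
    zc = ((X[:, :-1] * X[:, 1:] < 0) & (np.abs(d) > deadband)).sum(axis=1)
    d1, d2 = d[:, :-1], d[:, 1:]
    ssc = (
        (d1 * d2 < 0)
        & ((np.abs(d1) > deadband) | (np.abs(d2) > deadband))
    ).sum(axis=1)
    return np.column_stack((mav, zc, ssc, wl)).astype(np.float64)


def tdar_features(window: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """AR coefficients (Burg) plus RMS of one single-channel window.

    The coefficients follow the prediction convention
    ``x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t``.  A window with zero
    sample variance has undefined AR structure; its coefficients are
    returned as zeros.
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    if x.size <= order:
        raise ValueError(
            f"window of {x.size} samples cannot support an AR({order}) fit"
        )
    rms = float(np.sqrt(np.mean(x**2)))
    if np.ptp(x) == 0.0:
        return np.concatenate((np.zeros(order), [rms]))
    ar, _sigma2 = _burg(x, order=order, demean=True)
    return np.concatenate((ar, [rms]))


# ---------------------------------------------------------------------------
# matrix assembly


def build_feature_matrix(
    recording: EmgRecording,
    channel_ids,
    feature_set: str = "td",
    win_ms: float = 150.0,
    step_ms: float = 100.0,
    deadband: float = 0.0,
    ar_order: int = AR_ORDER,
) -> FeatureMatrix:
    """Segment a recording and extract features from the given channels.

    Column blocks follow the order of ``channel_ids``; within each block
    features appear in the fixed order of the feature set.
    """
    channel_ids = [int(c) for c in channel_ids]
    if not channel_ids:
        raise ValueError("channel_ids must be non-empty")
    if any(not 0 <= c < recording.n_channels for c in channel_ids):
        raise ValueError("channel id outside recording")
    feature_set = feature_set.lower()
    if feature_set not in FEATURES_PER_CHANNEL:
        raise ValueError(f"unknown feature set: {feature_set!r}")

    windows = segment_windows(recording, win_ms=win_ms, step_ms=step_ms)
    n_win = len(windows)
    fpc = (
        len(TD_FEATURE_NAMES) if feature_set == "td" else ar_order + 1
    )
    values = np.empty((n_win, len(channel_ids) * fpc))
    labels = np.array([w.label for w in windows], dtype=np.int64)
    if n_win == 0:
        return FeatureMatrix(values, labels, tuple(channel_ids), feature_set)

    starts = np.array([w.start for w in windows])
    L = windows[0].stop - windows[0].start
    idx = starts[:, None] + np.arange(L)[None, :]
    for b, c in enumerate(channel_ids):
        X = recording.signal[:, c][idx]  # (n_win, L)
        if feature_set == "td":
            values[:, b * fpc : (b + 1) * fpc] = _td_block(X, deadband)
        else:
            for i in range(n_win):
                values[i, b * fpc : (b + 1) * fpc] = tdar_features(
                    X[i], order=ar_order
                )
    return FeatureMatrix(values, labels, tuple(channel_ids), feature_set)
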