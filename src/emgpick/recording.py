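"""Core container for multichannel surface-EMG recordings.

A recording is a ``samples x channels`` float matrix together with its
sampling rate and two per-sample integer annotations: the movement-class
label and the trial index.  Trials are contiguous runs of samples; all
segment-aware operations (zero-phase filtering, window segmentation,
per-class covariance) iterate over those runs rather than the raw matrix
so that no computation ever straddles a trial boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


@dataclass
class TrialSegment:
    """One contiguous trial: half-open sample range plus its annotations."""

    start: int
    stop: int
    label: int
    trial_id: int

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class EmgRecording:
    """Multichannel EMG signal with per-sample class and trial annotations.

    Parameters
    ----------
    signal
        Array of shape ``(n_samples, n_channels)``, arbitrary amplitude units.
    fs
        Sampling rate in Hz.
    labels
        Integer class label per sample, shape ``(n_samples,)``.
    trial_ids
        Integer trial index per sample, shape ``(n_samples,)``.  Each trial
        must occupy a single contiguous run of samples.
    """

    signal: np.ndarray
    fs: float
    labels: np.ndarray
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D samples x channels array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[1] < 1:
            raise ValueError("recording needs at least one channel")
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.trial_ids is None:
            # single-trial-per-class convention: one trial per contiguous label run
            change = np.flatnonzero(np.diff(self.labels) != 0)
            ids = np.zeros(self.labels.size, dtype=np.int64)
            for k, c in enumerate(change, start=1):
                ids[c + 1 :] = k
            self.trial_ids = ids
        else:
            self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64).ravel()
        n = self.signal.shape[0]
        if self.labels.size != n or self.trial_ids.size != n:
            raise ValueError(
                "labels/trial_ids length "
                f"({self.labels.size}/{self.trial_ids.size}) does not match "
                f"sample count ({n})"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class labels present in the recording."""
        return np.unique(self.labels)

    def trial_segments(self) -> Iterator[TrialSegment]:
        """Yield contiguous trials in temporal order."""
        if self.n_samples == 0:
            return
        boundaries = np.flatnonzero(np.diff(self.trial_ids) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [self.n_samples]))
        for a, b in zip(starts, stops):
            yield TrialSegment(
                start=int(a),
                stop=int(b),
                label=int(self.labels[a]),
                trial_id=int(self.trial_ids[a]),
            )

    def with_signal(self, signal: np.ndarray) -> "EmgRecording":
        """Copy of this recording with ``signal`` replaced (same annotations)."""
        return EmgRecording(
            signal=signal,
            fs=self.fs,
            labels=self.labels.copy(),
            trial_ids=self.trial_ids.copy(),
        )

    def class_samples(self, label: int) -> np.ndarray:
        """All samples of one class, pooled across its trials."""
        mask = self.labels == int(label)
        if not mask.any():
            raise ValueError(f"unknown class label: {label}")
        return self.signal[mask]
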