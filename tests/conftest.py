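import numpy as np
import pytest

from emgpick import EmgRecording
from emgpick.synth import SynthConfig, generate_recording

# Planted maps used across the suite.  With one elevated channel per class
# the one-versus-rest pick rule can recover every planted channel; with two
# per class each class's first pattern can only claim one of its pair.
MAP_4x2 = {
    0: frozenset({1, 5}),
    1: frozenset({2, 9}),
    2: frozenset({3, 12}),
    3: frozenset({7, 14}),
}
MAP_8x1 = {c: frozenset({2 * c}) for c in range(8)}


@pytest.fixture(scope="session")
def rec_4x2():
    """4 classes x 2 planted channels, 16 channels, gain 5, full 6x6s trials."""
    cfg = SynthConfig(
        n_classes=4, n_channels=16, gain=5.0, informative_map=MAP_4x2, seed=0
    )
    rec, imap = generate_recording(cfg)
    return rec, imap


@pytest.fixture(scope="session")
def rec_8x1():
    """8 classes x 1 planted channel, 16 channels, gain 5, full 6x6s trials."""
    cfg = SynthConfig(
        n_classes=8, n_channels=16, gain=5.0, informative_map=MAP_8x1, seed=3
    )
    rec, imap = generate_recording(cfg)
    return rec, imap


@pytest.fixture(scope="session")
def small_rec():
    """Small 3-class, 8-channel recording for format/filter/feature tests."""
    cfg = SynthConfig(
        n_classes=3,
        n_channels=8,
        trial_s=2.0,
        n_trials=2,
        gain=3.0,
        informative_map={1: frozenset({2}), 2: frozenset({5})},
        seed=7,
    )
    rec, _ = generate_recording(cfg)
    return rec


def make_recording(signal, fs=1024.0, labels=None, trial_ids=None):
    n = signal.shape[0]
    if labels is None:
        labels = np.zeros(n, dtype=int)
    return EmgRecording(signal=signal, fs=fs, labels=labels, trial_ids=trial_ids)
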