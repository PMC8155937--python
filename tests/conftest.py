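import numpy as np
import pytest

from eegaffect import (
    AffectLabel,
    Epoch,
    GeneratorConfig,
    Recording,
    builtin_montage,
)

FS = 128.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def emotiv():
    return builtin_montage("emotiv14")


@pytest.fixture
def deap():
    return builtin_montage("deap32")


@pytest.fixture
def label_mid():
    return AffectLabel(valence_raw=5.0, arousal_raw=5.0)


def make_recording(montage, seconds=10.0, fs=FS, seed=0, labels=None):
    """Random multichannel recording with mild band structure."""
    rng = np.random.default_rng(seed)
    n = int(seconds * fs)
    t = np.arange(n) / fs
    data = np.empty((montage.n_channels, n))
    for c in range(montage.n_channels):
        data[c] = (
            rng.standard_normal(n)
            + 2.0 * np.sin(2 * np.pi * 10.1 * t + rng.uniform(0, 2 * np.pi))
            + 1.0 * np.sin(2 * np.pi * 21.3 * t + rng.uniform(0, 2 * np.pi))
        )
    return Recording(
        data=data,
        fs=fs,
        montage=montage,
        labels=labels or AffectLabel(6.0, 4.0),
        trial_id="t0",
        subject_id="s0",
    )


@pytest.fixture
def recording(emotiv):
    return make_recording(emotiv)


@pytest.fixture
def small_epochs(emotiv):
    """A handful of 4 s epochs from random recordings, for assembly tests."""
    rng = np.random.default_rng(7)
    epochs = []
    for i in range(4):
        data = rng.standard_normal((emotiv.n_channels, int(4 * FS)))
        epochs.append(
            Epoch(
                data=data,
                fs=FS,
                montage=emotiv,
                labels=AffectLabel(1 + 8 * rng.uniform(), 1 + 8 * rng.uniform()),
                trial_id=f"t{i}",
                subject_id="s0",
                epoch_index=0,
            )
        )
    return epochs
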