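import numpy as np
import pytest

from emgphasor.preprocess import WindowSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_windowset(
    rng,
    n_windows=20,
    n_channels=9,
    length=64,
    n_classes=5,
    n_trials=5,
    subject_id=0,
    fs=1000.0,
):
    """A WindowSet filled with Gaussian noise, for feature-level tests."""
    return WindowSet(
        windows=rng.standard_normal((n_windows, n_channels, length)),
        labels=rng.integers(0, n_classes, n_windows),
        trial_ids=np.repeat(np.arange(n_trials), int(np.ceil(n_windows / n_trials)))[:n_windows],
        subject_id=subject_id,
        fs=fs,
    )


@pytest.fixture
def winset(rng):
    return random_windowset(rng)
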