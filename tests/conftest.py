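import numpy as np
import pandas as pd
import pytest

from phasenet.montage import Montage, default_montage
from phasenet.preprocess import EpochSet


@pytest.fixture
def montage():
    return default_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(20130322)


@pytest.fixture
def tiny_montage():
    return Montage(labels=("C3", "C4", "Cz", "P3"))


def make_epochs(data, fs=1000.0, montage=None, meta=None, **kwargs):
    """Build an EpochSet with auto-generated montage/metadata."""
    data = np.asarray(data, dtype=float)
    n_trials, n_chan, _ = data.shape
    if montage is None:
        labels = tuple(f"C{2 * i + 1}" for i in range(n_chan))  # all left
        montage = Montage(labels=labels)
    if meta is None:
        meta = pd.DataFrame({
            "hand": ["left", "right"] * (n_trials // 2) + ["left"] * (n_trials % 2),
            "angle": [0] * n_trials,
            "correct": [True] * n_trials,
        })
    return EpochSet(data=data, fs=fs, montage=montage, meta=meta, **kwargs)


@pytest.fixture
def epochs_factory():
    return make_epochs
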