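import numpy as np
import pytest

from miattn.io_preprocess import TrialEpochs
from miattn.pipeline import RunConfig, preprocess_subject
from miattn.synthetic_data import SynthConfig, generate_subject

# compact montage for unit tests; every label exists in the template
SMALL_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "FC4", "Cz")


@pytest.fixture(scope="session")
def small_config():
    """Two sets of ten trials at the analysis rate (resampling is identity)."""
    return SynthConfig(n_subjects=2, n_sets=2, trials_per_set=10,
                       fs_raw=200.0, channel_labels=SMALL_CHANNELS, seed=42)


@pytest.fixture(scope="session")
def small_subject(small_config):
    return generate_subject(small_config, 0)


@pytest.fixture(scope="session")
def small_epochs(small_subject):
    raw, truth = small_subject
    return preprocess_subject(raw, RunConfig()), truth


def make_epochs(signals: dict, labels, fs: float = 200.0,
                tspan=(-2.0, 7.0)) -> TrialEpochs:
    """Build TrialEpochs from per-channel signal callables.

    ``signals`` maps channel label -> f(times, trial_index, label) array.
    """
    times = np.arange(tspan[0] * fs, tspan[1] * fs) / fs
    labels = np.asarray(labels, dtype=object)
    chans = tuple(signals)
    data = np.stack([
        np.stack([np.asarray(signals[ch](times, k, lab), dtype=float)
                  for ch in chans])
        for k, lab in enumerate(labels)])
    return TrialEpochs(data, fs, times, chans, labels)
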