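"""Raw-recording container, preprocessing and epoching.

The preprocessing chain mirrors a standard motor-imagery workflow:
resample 1000 -> 200 Hz, zero-phase band-pass 1-30 Hz, epoch around the
Select cue, label trials by key-press correctness, subtract the -1..0 s
baseline mean, and (for the alpha-modulation contrast) subsample the
majority class so both attention classes contribute equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import h5py
import numpy as np
from scipy import signal as sps

from .paradigm import ATTENTION, BASELINE, INATTENTION, TRIAL_SPAN

logger = logging.getLogger(__name__)

INVALID = "Invalid"


@dataclass(frozen=True)
class Event:
    """One trial marker: sample index of the Select cue plus behavior."""

    sample: int
    arrow: str
    response: str | None
    correct: bool | None = None

    def __post_init__(self):
        if self.correct is None:
            ok = self.response is not None and self.response == self.arrow
            object.__setattr__(self, "correct", ok if self.response is not None else None)


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts with trial markers."""

    samples: np.ndarray  # (n_channels, n_times), microvolts
    fs: float
    channel_labels: tuple[str, ...]
    events: list[Event] = field(default_factory=list)
    subject: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_channels, n_times)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel label count does not match data")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n = self.samples.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event at sample {ev.sample} outside record of {n}")

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None


@dataclass
class TrialEpochs:
    """Per-trial (trials x channels x time) arrays with condition labels.

    ``times`` is in seconds relative to the Select cue; the baseline window
    defaults to the -1..0 s resting second.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    channel_labels: tuple[str, ...]
    labels: np.ndarray  # array of str, one per trial
    baseline_window: tuple[float, float] = BASELINE
    subject: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match labels")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match data")
        if self.labels.size != self.data.shape[0]:
            raise ValueError("one label per trial required")
        b0, b1 = self.baseline_window
        if not (self.times[0] <= b0 < b1 <= self.times[-1] + 1.0 / self.fs):
            raise ValueError("baseline window must lie inside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def select(self, condition: str) -> "TrialEpochs":
        """Return the sub-epochs of one condition (view-copy of the data)."""
        mask = self.labels == condition
        return TrialEpochs(
            data=self.data[mask],
            fs=self.fs,
            times=self.times,
            channel_labels=self.channel_labels,
            labels=self.labels[mask],
            baseline_window=self.baseline_window,
            subject=self.subject,
        )


def label_attention(event: Event) -> str:
    """Label a trial by key-press correctness.

    Matching response -> Attention, mismatching -> Inattention.  A missing
    response is not evidence of inattention; the trial is flagged invalid
    and later dropped.
    """
    if event.response is None:
        return INVALID
    return ATTENTION if event.response == event.arrow else INATTENTION


def resample(raw: RawRecording, fs_target: float) -> RawRecording:
    """Polyphase anti-aliased resampling; event indices remap proportionally.

    Upsampling is rejected: the pipeline only ever reduces 1000 Hz
    acquisitions to the 200 Hz analysis rate.
    """
    if fs_target > raw.fs:
        raise ValueError("upsampling is not supported")
    if fs_target <= 0:
        raise ValueError("target rate must be positive")
    if fs_target == raw.fs:
        return replace(raw, samples=raw.samples.copy(), events=list(raw.events))
    frac = Fraction(fs_target / raw.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(raw.samples, up, down, axis=1)
    scale = fs_target / raw.fs
    n_out = out.shape[1]
    events = []
    for ev in raw.events:
        s = int(round(ev.sample * scale))
        if s >= n_out:
            logger.warning("event at %d fell off the resampled record", ev.sample)
            continue
        events.append(replace(ev, sample=s))
    return RawRecording(out, fs_target, raw.channel_labels, events, raw.subject)


def bandpass(raw: RawRecording, lo: float = 1.0, hi: float = 30.0,
             order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay)."""
    if not 0 < lo < hi < raw.fs / 2:
        raise ValueError(f"invalid band edges ({lo}, {hi}) at fs={raw.fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=raw.fs, output="sos")
    out = sps.sosfiltfilt(sos, raw.samples, axis=1)
    return RawRecording(out, raw.fs, raw.channel_labels, list(raw.events), raw.subject)


def epoch(raw: RawRecording, window: tuple[float, float] = TRIAL_SPAN,
          baseline_window: tuple[float, float] = BASELINE) -> TrialEpochs:
    """Cut one epoch per event, t = 0 at the Select cue.

    Events whose window exceeds the record bounds, and events with a
    missing response, are dropped with a logged count.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must be increasing")
    i0 = int(round(t0 * raw.fs))
    n_len = int(round((t1 - t0) * raw.fs))
    times = t0 + np.arange(n_len) / raw.fs
    trials, labels = [], []
    n_bounds = n_invalid = 0
    for ev in raw.events:
        lab = label_attention(ev)
        if lab == INVALID:
            n_invalid += 1
            continue
        a = ev.sample + i0
        b = a + n_len
        if a < 0 or b > raw.n_times:
            n_bounds += 1
            continue
        trials.append(raw.samples[:, a:b])
        labels.append(lab)
    if n_bounds or n_invalid:
        logger.warning(
            "dropped %d out-of-bounds and %d invalid-response trials "
            "(%d retained)", n_bounds, n_invalid, len(trials))
    if not trials:
        raise ValueError("no epochable events")
    data = np.stack(trials)
    return TrialEpochs(data, raw.fs, times, raw.channel_labels,
                       np.array(labels, dtype=object), baseline_window,
                       raw.subject)


def baseline_correct(epochs: TrialEpochs) -> TrialEpochs:
    """Subtract the per-trial, per-channel mean of the baseline segment."""
    b0, b1 = epochs.baseline_window
    mask = (epochs.times >= b0) & (epochs.times < b1)
    if not mask.any():
        raise ValueError("degenerate baseline window")
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return TrialEpochs(epochs.data - mean, epochs.fs, epochs.times,
                       epochs.channel_labels, epochs.labels,
                       epochs.baseline_window, epochs.subject)


def balance_trials(epochs: TrialEpochs, seed: int) -> TrialEpochs:
    """Subsample the majority class, without replacement, to the minority count.

    Deterministic under ``seed``; the minority class is untouched and every
    retained trial's data is bit-identical to its original.
    """
    labels = epochs.labels
    counts = {c: int(np.sum(labels == c)) for c in (ATTENTION, INATTENTION)}
    for c, n in counts.items():
        if n == 0:
            raise ValueError(f"cannot balance: no {c} trials")
    if counts[ATTENTION] == counts[INATTENTION]:
        return epochs
    major = max(counts, key=counts.get)
    minor_n = min(counts.values())
    rng = np.random.default_rng(seed)
    major_idx = np.flatnonzero(labels == major)
    keep_major = rng.choice(major_idx, size=minor_n, replace=False)
    keep = np.sort(np.concatenate([keep_major, np.flatnonzero(labels != major)]))
    return TrialEpochs(epochs.data[keep], epochs.fs, epochs.times,
                       epochs.channel_labels, labels[keep],
                       epochs.baseline_window, epochs.subject)


def ica_artifact_removal(raw: RawRecording, backend=None) -> RawRecording:
    """Optional artifact-removal hook (disabled by default).

    Ocular/muscle artifact rejection by ICA component classification is
    delegated to an external ``backend`` callable mapping RawRecording ->
    RawRecording.  With no backend the recording passes through unchanged.
    """
    if backend is None:
        return raw
    return backend(raw)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_epochs(path, epochs: TrialEpochs) -> None:
    """Persist epochs to HDF5 (datasets: data, labels, fs, times, channels)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("labels",
                         data=np.array([s.encode() for s in epochs.labels]))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channels",
                         data=np.array([s.encode() for s in epochs.channel_labels]))
        f.attrs["fs"] = epochs.fs
        f.attrs["baseline_window"] = epochs.baseline_window
        f.attrs["subject"] = epochs.subject


def load_epochs(path) -> TrialEpochs:
    with h5py.File(path, "r") as f:
        return TrialEpochs(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            times=f["times"][()],
            channel_labels=tuple(s.decode() for s in f["channels"][()]),
            labels=np.array([s.decode() for s in f["labels"][()]], dtype=object),
            baseline_window=tuple(f.attrs["baseline_window"]),
            subject=str(f.attrs["subject"]),
        )
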