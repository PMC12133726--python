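"""Attention indices: alpha modulation index (AMI) and theta/beta ratio (TBR).

AMI is a normalised contrast of FFT-derived alpha power at a right-frontal
electrode (F4 by default) between correct-selection ("right") and
incorrect-selection ("wrong") trials,

    AMI = (a_AR - a_AW) / (a_AR + a_AW)   in [-1, 1],

computed after subsampling the majority class so both groups contribute
equally.  Under the correctness-based labeling rule the right/wrong groups
coincide with the Attention/Inattention conditions.

TBR is the ratio of theta-band to beta-band wavelet-packet energy,

    TBR = E_theta / E_beta ;

a decrease signals attention.  Offline, TBR is evaluated on sliding 1-s
windows over the epoch; online, on 1-s buffers as they arrive, one value
per second with no look-ahead.  Both paths share one computation, so they
agree bit-for-bit on identical windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_preprocess import TrialEpochs, balance_trials
from .paradigm import (ALPHA_BAND, ATTENTION, BETA_BAND, CONDITIONS,
                       INATTENTION, MI, THETA_BAND)
from .spectral import alpha_power_fft, band_node_mask, packet_band_energies

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlphaPowers:
    """FFT alpha-band powers of the right- and wrong-selection groups."""

    a_right: float
    a_wrong: float
    electrode: str = "F4"

    def __post_init__(self):
        if self.a_right < 0 or self.a_wrong < 0:
            raise ValueError("powers must be non-negative")
        if self.a_right + self.a_wrong == 0:
            raise ValueError("AMI undefined: both group powers are zero")


@dataclass
class SubjectIndices:
    """One subject-condition row of the summary tables."""

    subject: str
    condition: str
    erd: float | None = None
    ami: float | None = None
    tbr: float | None = None


@dataclass
class TBRSeries:
    """Per-second TBR values; stamps mark each window's end (causal)."""

    times: np.ndarray
    values: np.ndarray
    condition: str = ""
    mode: str = "offline_continuous"  # or "online_buffered"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must align")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")


def ami(a_right: float, a_wrong: float) -> float:
    """Alpha modulation index (a_AR - a_AW) / (a_AR + a_AW)."""
    if a_right < 0 or a_wrong < 0:
        raise ValueError("powers must be non-negative")
    total = a_right + a_wrong
    if total == 0:
        raise ValueError("AMI undefined: both powers are zero")
    return (a_right - a_wrong) / total


def tbr(e_theta: float, e_beta: float) -> float:
    """Theta/beta energy ratio."""
    if e_beta <= 0:
        raise ValueError("beta-band energy must be positive")
    return e_theta / e_beta


def subject_ami(epochs: TrialEpochs, electrode: str = "F4", seed: int = 0,
                band: tuple[float, float] = ALPHA_BAND,
                mi_window: tuple[float, float] = MI) -> dict:
    """Per-condition AMI of one subject at one electrode.

    Trials are class-balanced (deterministic under ``seed``), alpha power
    is the FFT band power of each trial's motor-imagery segment averaged
    within the correct/incorrect groups, and the index is reported in both
    orientations: the Inattention entry is the antisymmetric counterpart
    of the Attention one (the same contrast seen from the other side).
    """
    bal = balance_trials(epochs, seed)
    ci = bal.channel_index(electrode)
    tmask = (bal.times >= mi_window[0]) & (bal.times < mi_window[1])
    powers = {}
    for cond in CONDITIONS:
        sub = bal.data[bal.labels == cond][:, ci][:, tmask]
        powers[cond] = float(np.mean(
            [alpha_power_fft(trial, bal.fs, band) for trial in sub]))
    value = ami(powers[ATTENTION], powers[INATTENTION])
    return {
        ATTENTION: value,
        INATTENTION: -value,
        "powers": AlphaPowers(powers[ATTENTION], powers[INATTENTION], electrode),
    }


def _window_tbr(buffers: np.ndarray, fs: float, wavelet: str, level: int,
                theta_band: tuple[float, float],
                beta_band: tuple[float, float]) -> np.ndarray:
    """TBR of 1-s windows; shared by the offline and online paths."""
    energies = packet_band_energies(buffers, wavelet, level)
    th = band_node_mask(fs, level, theta_band)
    be = band_node_mask(fs, level, beta_band)
    e_theta = energies[..., th].sum(axis=-1)
    e_beta = energies[..., be].sum(axis=-1)
    return e_theta / e_beta


def tbr_offline_series(epochs: TrialEpochs, channel: str = "Cz",
                       step: float = 1.0, window: float = 1.0,
                       span: tuple[float, float] = (-1.0, 5.0),
                       *, wavelet: str = "db4", level: int = 8,
                       theta_band: tuple[float, float] = THETA_BAND,
                       beta_band: tuple[float, float] = BETA_BAND) -> dict:
    """Continuous per-window TBR per condition, trial-averaged.

    Windows of ``window`` seconds start at ``span[0]`` and advance by
    ``step``; each series value is the mean over that condition's trials
    of the per-trial window TBR, stamped at the window end.
    """
    if span[0] < epochs.times[0] - 1e-9 or span[1] > epochs.times[-1] + 1.0 / epochs.fs + 1e-9:
        raise ValueError("requested span lies outside the epoch")
    fs = epochs.fs
    n_win = int(round(window * fs))
    starts = []
    t = span[0]
    while t + window <= span[1] + 1e-9:
        starts.append(t)
        t += step
    ci = epochs.channel_index(channel)
    out = {}
    for cond in CONDITIONS:
        sub = epochs.data[epochs.labels == cond][:, ci, :]
        if sub.shape[0] == 0:
            continue
        vals = np.empty(len(starts))
        for i, s in enumerate(starts):
            i0 = int(round((s - epochs.times[0]) * fs))
            seg = sub[:, i0:i0 + n_win]
            vals[i] = _window_tbr(seg, fs, wavelet, level,
                                  theta_band, beta_band).mean()
        stamps = np.asarray(starts) + window
        out[cond] = TBRSeries(stamps, vals, cond, "offline_continuous")
    return out


def tbr_online(buffers, fs: float, channel_index: int | None = None,
               *, wavelet: str = "db4", level: int = 8,
               theta_band: tuple[float, float] = THETA_BAND,
               beta_band: tuple[float, float] = BETA_BAND,
               t0: float = 0.0) -> TBRSeries:
    """One TBR value per arriving 1-s buffer, no look-ahead.

    ``buffers`` is an iterable of arrays of ``fs`` samples (optionally
    (channels, fs), selected by ``channel_index``).  A short or malformed
    buffer is skipped with a logged warning, leaving a gap in the series.
    Values are numerically identical to :func:`tbr_offline_series` run
    with non-overlapping 1-s windows over the same samples.
    """
    n_expect = int(round(fs))
    times, values = [], []
    for k, buf in enumerate(buffers):
        try:
            buf = np.asarray(buf, dtype=float)
            if buf.ndim == 2:
                if channel_index is None:
                    raise ValueError("multichannel buffer needs channel_index")
                buf = buf[channel_index]
            if buf.ndim != 1 or buf.size != n_expect or not np.isfinite(buf).all():
                raise ValueError(f"buffer of {buf.size} samples, expected {n_expect}")
        except ValueError as err:
            logger.warning("skipping buffer %d: %s", k, err)
            continue
        values.append(float(_window_tbr(buf, fs, wavelet, level,
                                        theta_band, beta_band)))
        times.append(t0 + (k + 1) * 1.0)
    return TBRSeries(np.array(times), np.array(values),
                     mode="online_buffered")


def subject_tbr(epochs: TrialEpochs, channel: str = "Cz",
                span: tuple[float, float] = MI, **kwargs) -> dict:
    """Per-condition mean TBR over the motor-imagery interval (Table row)."""
    series = tbr_offline_series(epochs, channel, step=1.0, window=1.0,
                                span=span, **kwargs)
    return {cond: float(s.values.mean()) for cond, s in series.items()}
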