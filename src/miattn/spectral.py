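"""Wavelet-packet time-frequency analysis: ERSP maps, ERD and energy curves.

Spectral estimation uses a short-time wavelet-packet transform: the signal
is cut into sliding windows of ``2**level`` samples (1.28 s at 200 Hz,
level 8) and each window is decomposed with an orthogonal wavelet packet
(``db4`` by default, ``mode='periodization'``), giving one coefficient per
terminal node, i.e. a spectrum with ``fs / 2**(level+1)`` Hz bins
(0.39 Hz).  Energy is conserved exactly (orthonormal transform), so summed
squared coefficients are band energies.

The event-related spectral perturbation (ERSP) is the power averaged over
trials,

    ERSP(f, t) = (1/N) * sum_k |K(f, t, k)|^2 ,

converted to dB relative to the mean power of the same frequency row over
the -1..0 s baseline.  The event-related desynchronization (ERD) scalar is
the plain mean of the dB map over a frequency x time window (alpha band x
motor-imagery interval by convention), so an injected alpha-amplitude
suppression of depth d is recovered as 20*log10(1 - d) dB.

Note on the default wavelet: db4's short filters alias roughly a fifth of
a mid-alpha tone's energy into neighbouring bands.  Band-*ratio* measures
(ERSP in dB, ERD, TBR) are unaffected because the capture factor cancels,
but absolute band-energy concentration improves markedly with longer
wavelets (e.g. ``db16``), which any entry point accepts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

from .paradigm import ALPHA_BAND, BASELINE, MI

_EPS = 1e-300


@lru_cache(maxsize=8)
def _freq_order(wavelet: str, level: int) -> np.ndarray:
    """Natural->frequency ordering permutation of the terminal nodes."""
    wp = pywt.WaveletPacket(np.zeros(2 ** level), wavelet,
                            mode="periodization", maxlevel=level)
    natural = [nd.path for nd in wp.get_level(level, order="natural")]
    freq = [nd.path for nd in wp.get_level(level, order="freq")]
    index = {p: i for i, p in enumerate(natural)}
    return np.array([index[p] for p in freq])


def packet_node_freqs(fs: float, level: int) -> np.ndarray:
    """Center frequencies (Hz) of the 2**level terminal nodes."""
    width = fs / 2.0 / 2 ** level
    return (np.arange(2 ** level) + 0.5) * width


def packet_band_energies(x: np.ndarray, wavelet: str = "db4",
                         level: int = 8) -> np.ndarray:
    """Per-node energies of a wavelet-packet decomposition, frequency order.

    ``x`` has shape (..., n); signals shorter than a multiple of
    ``2**level`` are zero-padded (the transform stays orthonormal, so total
    energy is preserved exactly).  Returns shape (..., 2**level).
    """
    x = np.asarray(x, dtype=float)
    m = 2 ** level
    n = x.shape[-1]
    if n == 0:
        raise ValueError("empty signal")
    if n % m:
        pad = m - n % m
        x = np.concatenate([x, np.zeros(x.shape[:-1] + (pad,))], axis=-1)
    arrs = [x]
    for _ in range(level):
        nxt = []
        for a in arrs:
            ca, cd = pywt.dwt(a, wavelet, mode="periodization", axis=-1)
            nxt.append(ca)
            nxt.append(cd)
        arrs = nxt
    energies = np.stack([np.sum(a * a, axis=-1) for a in arrs], axis=-1)
    return energies[..., _freq_order(wavelet, level)]


def band_node_mask(fs: float, level: int, band: tuple[float, float]
                   ) -> np.ndarray:
    """Terminal nodes whose center frequency falls in [f1, f2)."""
    f = packet_node_freqs(fs, level)
    return (f >= band[0]) & (f < band[1])


@dataclass(frozen=True)
class BandWindow:
    """A frequency x time rectangle: [f1, f2) Hz by [t1, t2] s."""

    f1: float
    f2: float
    t1: float
    t2: float

    def __post_init__(self):
        if not (self.f1 < self.f2 and self.t1 < self.t2):
            raise ValueError("window bounds must be increasing")


ALPHA_MI_WINDOW = BandWindow(*ALPHA_BAND, *MI)


@dataclass
class ERSPMap:
    """Trial-averaged time-frequency map in dB relative to baseline.

    ``window_s`` records the half-width of the analysis window behind each
    time bin, so window selections can demand full support.
    """

    values: np.ndarray  # (n_freqs, n_times), dB
    freqs: np.ndarray  # bin-center Hz, strictly increasing
    times: np.ndarray  # bin-center s, strictly increasing
    channel: str
    condition: str
    n_trials: int
    window_s: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("map shape does not match axes")
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("axes must be strictly increasing")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")

    def window_bins(self, win: BandWindow, full_support: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Row and column masks selected by a BandWindow.

        Frequency rows are selected by bin center in [f1, f2).  Time bins
        by default require the full analysis-window support inside
        [t1, t2]; with ``full_support=False`` the bin center suffices.
        """
        rows = (self.freqs >= win.f1) & (self.freqs < win.f2)
        if full_support:
            cols = ((self.times - self.window_s >= win.t1 - 1e-9)
                    & (self.times + self.window_s <= win.t2 + 1e-9))
        else:
            cols = (self.times >= win.t1) & (self.times < win.t2)
        return rows, cols


def _window_centers(times: np.ndarray, fs: float, half: float,
                    hop_s: float, tmin: float, tmax: float) -> np.ndarray:
    lo = max(tmin, times[0] + half)
    hi = min(tmax, times[-1] + 1.0 / fs - half)
    first = np.ceil((lo - tmin) / hop_s - 1e-9) * hop_s + tmin
    return np.arange(first, hi + 1e-9, hop_s)


def _window_power(data: np.ndarray, times: np.ndarray, fs: float,
                  centers: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Sliding-window packet power.  data (..., n_time) -> (..., n_centers, nodes)."""
    m = 2 ** level
    starts = np.round((centers - m / 2.0 / fs - times[0]) * fs).astype(int)
    windows = np.stack([data[..., s:s + m] for s in starts], axis=-2)
    return packet_band_energies(windows, wavelet, level)


def trial_spectrogram(signal: np.ndarray, fs: float,
                      band: tuple[float, float] = (1.0, 30.0),
                      *, wavelet: str = "db4", level: int = 8,
                      hop_s: float = 0.25, times: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time wavelet-packet power of one trial's channel signal.

    Returns ``(power, freqs, t_centers)`` where power is
    (n_freq_rows, n_windows), rows are the 0.39 Hz packet bins whose
    centers fall inside ``band``.
    """
    signal = np.asarray(signal, dtype=float)
    m = 2 ** level
    if signal.size < m:
        raise ValueError(
            f"level {level} needs at least {m} samples, got {signal.size}")
    if times is None:
        times = np.arange(signal.size) / fs
    half = m / 2.0 / fs
    centers = _window_centers(times, fs, half, hop_s, times[0], times[-1])
    power = _window_power(signal, times, fs, centers, wavelet, level)
    rows = band_node_mask(fs, level, band)
    freqs = packet_node_freqs(fs, level)[rows]
    return power[..., rows].T, freqs, centers


def ersp(epochs, channel: str, condition: str,
         *, band: tuple[float, float] = (1.0, 30.0),
         tlim: tuple[float, float] = (-1.0, 5.0),
         baseline: tuple[float, float] = BASELINE,
         wavelet: str = "db4", level: int = 8, hop_s: float = 0.25
         ) -> ERSPMap:
    """Trial-averaged ERSP map of one channel/condition, dB re baseline.

    Per-trial window powers are averaged across trials first; the dB
    reference is the per-frequency mean power over the baseline time bins
    (bins whose *centers* fall in the baseline window -- a 1.28 s analysis
    window cannot sit wholly inside a 1 s baseline).
    """
    sub = epochs.select(condition)
    if sub.n_trials == 0:
        raise ValueError(f"no {condition} trials")
    data = sub.data[:, sub.channel_index(channel), :]  # (trials, time)
    fs = sub.fs
    m = 2 ** level
    if data.shape[-1] < m:
        raise ValueError(f"epoch too short for level {level}")
    half = m / 2.0 / fs
    centers = _window_centers(sub.times, fs, half, hop_s, tlim[0], tlim[1])
    power = _window_power(data, sub.times, fs, centers, wavelet, level)
    mean_power = power.mean(axis=0)  # (n_centers, nodes)  -- Eq: 1/N sum |K|^2
    rows = band_node_mask(fs, level, band)
    freqs = packet_node_freqs(fs, level)[rows]
    mat = mean_power[:, rows].T  # (freq, time)
    base_cols = (centers >= baseline[0]) & (centers < baseline[1])
    if not base_cols.any():
        raise ValueError("no time bins inside the baseline window")
    ref = mat[:, base_cols].mean(axis=1, keepdims=True)
    values = 10.0 * np.log10((mat + _EPS) / (ref + _EPS))
    return ERSPMap(values, freqs, centers, channel, condition,
                   sub.n_trials, window_s=half)


def erd(map: ERSPMap, win: BandWindow = ALPHA_MI_WINDOW) -> float:
    """Mean of the ERSP dB values over a band window (M = bins in window)."""
    rows, cols = map.window_bins(win)
    if not rows.any() or not cols.any():
        raise ValueError("window selects no bins of the map")
    return float(map.values[np.ix_(rows, cols)].mean())


@dataclass
class EnergyCurve:
    """A 1-D collapse of ERSP maps: energy vs frequency or vs time (dB)."""

    axis: np.ndarray
    values: np.ndarray
    mode: str  # "over_time" (curve vs frequency) or "over_frequency"
    condition: str = ""
    n_subjects: int = 1


def energy_curve(maps: list[ERSPMap], mode: str,
                 band: tuple[float, float] = ALPHA_BAND,
                 twin: tuple[float, float] = MI) -> EnergyCurve:
    """Collapse ERSP maps to an energy curve, then average across subjects.

    ``over_time``: mean across the task-interval time bins per frequency.
    ``over_frequency``: mean across the band's frequency rows per time bin.
    """
    if not maps:
        raise ValueError("no maps given")
    ref = maps[0]
    for m in maps[1:]:
        if (m.freqs.shape != ref.freqs.shape
                or not np.allclose(m.freqs, ref.freqs)
                or not np.allclose(m.times, ref.times)):
            raise ValueError("maps must share axes")
    stack = np.stack([m.values for m in maps])
    win = BandWindow(band[0], band[1], twin[0], twin[1])
    rows, cols = ref.window_bins(win)
    if mode == "over_time":
        curve = stack[:, :, cols].mean(axis=2).mean(axis=0)
        axis = ref.freqs
    elif mode == "over_frequency":
        curve = stack[:, rows, :].mean(axis=1).mean(axis=0)
        axis = ref.times
    else:
        raise ValueError("mode must be 'over_time' or 'over_frequency'")
    return EnergyCurve(axis, curve, mode, ref.condition, len(maps))


def alpha_power_fft(signal: np.ndarray, fs: float,
                    band: tuple[float, float] = ALPHA_BAND) -> float:
    """Band power of a segment from its FFT periodogram.

    Sum of periodogram ordinates over bins in [f1, f2), normalised so the
    full-spectrum sum equals the signal's mean-square power.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n == 0:
        raise ValueError("empty signal")
    if band[0] >= fs / 2:
        raise ValueError("band lies beyond Nyquist")
    spec = np.abs(np.fft.rfft(signal)) ** 2 / n ** 2
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    f = np.fft.rfftfreq(n, 1.0 / fs)
    m = (f >= band[0]) & (f < band[1])
    return float(spec[m].sum())
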