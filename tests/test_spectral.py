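"""Wavelet-packet spectral estimation: energy conservation, ERSP, ERD."""

import numpy as np
import pytest

from miattn.paradigm import ATTENTION
from miattn.spectral import (BandWindow, ERSPMap, alpha_power_fft,
                             band_node_mask, energy_curve, erd, ersp,
                             packet_band_energies, packet_node_freqs,
                             trial_spectrogram)

from conftest import make_epochs

FS = 200.0


def _tone(freq, dur=1.28, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)


# ---------------------------------------------------------------------------
# packet transform
# ---------------------------------------------------------------------------

def test_parseval_energy_conservation():
    rng = np.random.default_rng(0)
    x = rng.normal(size=512)
    e = packet_band_energies(x, "db4", 8)
    assert abs(e.sum() - np.sum(x * x)) < 1e-8 * np.sum(x * x)


def test_parseval_with_zero_padding():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)  # padded to 256 internally
    e = packet_band_energies(x, "db4", 8)
    assert abs(e.sum() - np.sum(x * x)) < 1e-8 * np.sum(x * x)


def test_batched_equals_single():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(5, 256))
    batch = packet_band_energies(X, "db4", 8)
    singles = np.stack([packet_band_energies(x, "db4", 8) for x in X])
    assert np.array_equal(batch, singles)


@pytest.mark.parametrize("wavelet,minimum", [("db4", 0.75), ("db16", 0.90)])
def test_alpha_tone_concentration(wavelet, minimum):
    """A 10 Hz tone concentrates in the 8-13 Hz rows; short filters (db4)
    alias part of the energy into neighbouring bands, longer ones don't."""
    power, freqs, _ = trial_spectrogram(_tone(10.0, dur=9.0), FS,
                                        band=(1.0, 30.0), wavelet=wavelet)
    total = power.sum()
    in_band = power[(freqs >= 8) & (freqs < 13)].sum()
    assert in_band / total >= minimum


def test_zero_signal_zero_matrix():
    power, _, _ = trial_spectrogram(np.zeros(1800), FS)
    assert np.all(power == 0)


def test_two_tone_band_separation():
    sig = _tone(6.0, dur=9.0) + _tone(20.0, dur=9.0)
    power, freqs, _ = trial_spectrogram(sig, FS)
    total = power.sum()
    theta = power[(freqs >= 4) & (freqs < 8)].sum() / total
    alpha = power[(freqs >= 8) & (freqs < 13)].sum() / total
    beta = power[(freqs >= 13) & (freqs < 30)].sum() / total
    assert theta > 0.35 and beta > 0.35
    assert alpha < 0.06


def test_level_too_deep_rejected():
    with pytest.raises(ValueError):
        trial_spectrogram(np.ones(100), FS, level=8)


# ---------------------------------------------------------------------------
# ERSP / ERD
# ---------------------------------------------------------------------------

def test_ersp_stationary_signal_is_flat_zero_db():
    """Constant power over baseline and task -> 0 dB in signal rows."""
    ep = make_epochs({"Cz": lambda t, k, lab: np.sin(2 * np.pi * 10 * t)},
                     [ATTENTION])
    m = ersp(ep, "Cz", ATTENTION)
    rows = (m.freqs >= 9) & (m.freqs < 11)
    assert np.abs(m.values[rows]).max() < 0.6


def test_ersp_suppression_recovers_closed_form():
    """Alpha amplitude x0.6 during MI -> alpha rows at 20*log10(0.6) dB."""
    rng = np.random.default_rng(3)

    def cz(t, k, lab):
        from scipy import signal as sps
        sos = sps.butter(4, (7.25, 13.75), btype="bandpass", fs=FS,
                         output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(t.size))
        x /= x.std()
        env = np.where((t >= 1) & (t < 5), 0.6, 1.0)
        return env * x

    ep = make_epochs({"Cz": cz}, [ATTENTION] * 30)
    m = ersp(ep, "Cz", ATTENTION)
    value = erd(m, BandWindow(8, 13, 1, 5))
    assert abs(value - 20 * np.log10(0.6)) < 0.4


def test_ersp_mean_of_identical_trials():
    ep1 = make_epochs({"Cz": lambda t, k, lab: np.sin(2 * np.pi * 9 * t)},
                      [ATTENTION])
    ep5 = make_epochs({"Cz": lambda t, k, lab: np.sin(2 * np.pi * 9 * t)},
                      [ATTENTION] * 5)
    m1 = ersp(ep1, "Cz", ATTENTION)
    m5 = ersp(ep5, "Cz", ATTENTION)
    assert m5.n_trials == 5
    assert np.allclose(m1.values, m5.values)


def test_ersp_invariant_under_trial_reordering(small_epochs):
    ep, _ = small_epochs
    m = ersp(ep, "Cz", ATTENTION)
    idx = np.arange(ep.n_trials)[::-1]
    flipped = type(ep)(ep.data[idx], ep.fs, ep.times, ep.channel_labels,
                       ep.labels[idx], ep.baseline_window)
    m2 = ersp(flipped, "Cz", ATTENTION)
    assert np.allclose(m.values, m2.values)


def test_ersp_white_noise_is_flat():
    rng = np.random.default_rng(4)
    ep = make_epochs({"Cz": lambda t, k, lab: rng.standard_normal(t.size)},
                     [ATTENTION] * 100)
    m = ersp(ep, "Cz", ATTENTION)
    assert abs(m.values.mean()) < 0.5


def test_ersp_requires_trials(small_epochs):
    ep, _ = small_epochs
    with pytest.raises(ValueError):
        ersp(ep, "Cz", "NoSuchCondition")


def _const_map(value, cond=ATTENTION):
    freqs = np.arange(1, 30, 0.5)
    times = np.arange(-1, 5.01, 0.25)
    return ERSPMap(np.full((freqs.size, times.size), float(value)),
                   freqs, times, "Cz", cond, 10, window_s=0.64)


def test_erd_of_constant_map():
    assert erd(_const_map(-2.0), BandWindow(8, 13, 1, 5)) == -2.0


def test_erd_window_mean_arithmetic():
    m = _const_map(0.0)
    m.values[m.freqs < 10] = -4.0
    value = erd(m, BandWindow(8, 12, 1, 5))
    assert abs(value - -2.0) < 1e-12


def test_erd_empty_window_rejected():
    with pytest.raises(ValueError):
        erd(_const_map(1.0), BandWindow(40, 50, 1, 5))


def test_erd_linear_in_map():
    m = _const_map(0.0)
    rng = np.random.default_rng(5)
    m.values = rng.normal(size=m.values.shape)
    w = BandWindow(8, 13, 1, 5)
    a = erd(m, w)
    m2 = _const_map(0.0)
    m2.values = 2.0 * m.values
    assert abs(erd(m2, w) - 2 * a) < 1e-12


# ---------------------------------------------------------------------------
# energy curves
# ---------------------------------------------------------------------------

def test_energy_curve_constant_map_is_flat():
    c = energy_curve([_const_map(-1.5)], "over_time")
    assert np.allclose(c.values, -1.5)


def test_energy_curve_single_map_equals_collapse():
    m = _const_map(0.0)
    rng = np.random.default_rng(6)
    m.values = rng.normal(size=m.values.shape)
    c = energy_curve([m], "over_frequency", band=(8, 13))
    rows = (m.freqs >= 8) & (m.freqs < 13)
    assert np.allclose(c.values, m.values[rows].mean(axis=0))


def test_energy_curve_orders_conditions():
    att = [_const_map(-4.0), _const_map(-3.0)]
    inatt = [_const_map(-0.5, "Inattention"), _const_map(0.0, "Inattention")]
    ca = energy_curve(att, "over_time", band=(8, 13))
    ci = energy_curve(inatt, "over_time", band=(8, 13))
    assert np.all(ca.values < ci.values)


def test_energy_curve_axis_mismatch():
    m1 = _const_map(0.0)
    m2 = ERSPMap(np.zeros((3, 3)), np.array([1., 2, 3]),
                 np.array([0., 1, 2]), "Cz", ATTENTION, 1)
    with pytest.raises(ValueError):
        energy_curve([m1, m2], "over_time")


# ---------------------------------------------------------------------------
# FFT band power
# ---------------------------------------------------------------------------

def test_alpha_power_parseval():
    sig = _tone(10.0, dur=4.0)
    band = alpha_power_fft(sig, FS, (8, 13))
    total = np.mean(sig ** 2)
    assert abs(band - total) / total < 0.05


def test_alpha_power_out_of_band_rejection():
    sig = _tone(20.0, dur=4.0)
    band = alpha_power_fft(sig, FS, (8, 13))
    assert band <= 0.01 * np.mean(sig ** 2)


def test_alpha_power_zero_signal():
    assert alpha_power_fft(np.zeros(800), FS) == 0.0


def test_alpha_power_band_beyond_nyquist():
    with pytest.raises(ValueError):
        alpha_power_fft(np.ones(100), FS, (150, 160))


def test_node_freqs_cover_band():
    f = packet_node_freqs(FS, 8)
    assert f.size == 256
    mask = band_node_mask(FS, 8, (8, 13))
    assert f[mask].min() >= 8 - 0.4 and f[mask].max() < 13
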