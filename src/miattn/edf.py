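"""Minimal EDF+C writing and mne-backed reading.

The writer emits standard 16-bit EDF+C with one ``EDF Annotations`` signal
carrying the trial markers as time-stamped annotation lists (TALs); each
annotation encodes the arrow direction, the key response and its
correctness.  Reading goes through :func:`mne.io.read_raw_edf`, so any
EDF+ file with such annotations is accepted, not only our own.
"""

from __future__ import annotations

import math
import re

import numpy as np

from .io_preprocess import Event, RawRecording

_ANNOT_RE = re.compile(
    r"trial arrow=(?P<arrow>\S+) response=(?P<resp>\S+) correct=(?P<corr>\S+)")


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field too long: {text!r}")
    return b.ljust(width)


def event_description(ev: Event) -> str:
    resp = ev.response if ev.response is not None else "none"
    corr = {True: "1", False: "0", None: "na"}[ev.correct]
    return f"trial arrow={ev.arrow} response={resp} correct={corr}"


def write_edf(path, raw: RawRecording) -> None:
    """Write a RawRecording as EDF+C (16-bit, 1 s data records)."""
    fs = raw.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch = len(raw.channel_labels)
    n_rec = math.ceil(raw.n_times / spr)
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : raw.n_times] = raw.samples

    absmax = float(np.abs(data).max())
    phys = max(1.0, math.ceil(absmax))
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")

    # one TAL block per record: record timestamp, then any events inside it
    tals: list[bytes] = []
    by_record: dict[int, list[Event]] = {}
    for ev in raw.events:
        by_record.setdefault(int(ev.sample // spr), []).append(ev)
    for r in range(n_rec):
        block = f"+{r}\x14\x14\x00".encode("ascii")
        for ev in by_record.get(r, []):
            onset = ev.sample / fs
            block += f"+{onset:.6f}\x14{event_description(ev)}\x14\x00".encode("ascii")
        tals.append(block)
    annot_bytes = max(len(b) for b in tals) + 2
    annot_spr = (annot_bytes + 1) // 2  # 2-byte "samples"

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_ch + 2)), 8),
        _field("EDF+C", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch + 1), 4),
    ])
    labels = [_field(lab, 16) for lab in raw.channel_labels]
    labels.append(_field("EDF Annotations", 16))
    transducer = [_field("", 80)] * (n_ch + 1)
    phys_dim = [_field("uV", 8)] * n_ch + [_field("", 8)]
    phys_min = [_field(f"{-phys:g}", 8)] * n_ch + [_field("-32768", 8)]
    phys_max = [_field(f"{phys:g}", 8)] * n_ch + [_field("32767", 8)]
    d_min = [_field(str(dig_min), 8)] * (n_ch + 1)
    d_max = [_field(str(dig_max), 8)] * (n_ch + 1)
    prefilt = [_field("", 80)] * (n_ch + 1)
    n_samp = [_field(str(spr), 8)] * n_ch + [_field(str(annot_spr), 8)]
    reserved = [_field("", 32)] * (n_ch + 1)
    for group in (labels, transducer, phys_dim, phys_min, phys_max,
                  d_min, d_max, prefilt, n_samp, reserved):
        header += b"".join(group)

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            f.write(digital[:, r * spr:(r + 1) * spr].tobytes())
            f.write(tals[r].ljust(annot_spr * 2, b"\x00"))


def read_edf(path) -> RawRecording:
    """Read an EDF+ file with trial annotations into a RawRecording."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    samples = raw.get_data() * 1e6  # Volt -> microvolt
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        m = _ANNOT_RE.match(desc)
        if m is None:
            continue
        resp = None if m["resp"] == "none" else m["resp"]
        corr = {"1": True, "0": False, "na": None}[m["corr"]]
        events.append(Event(int(round(onset * fs)), m["arrow"], resp, corr))
    if not events:
        raise ValueError(f"no events: {path} carries no trial annotations")
    return RawRecording(samples, fs, tuple(raw.ch_names), events)
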