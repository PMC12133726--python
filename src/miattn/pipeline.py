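"""End-to-end orchestration: synthetic or file-based runs, tables, figures.

``run_offline`` executes generate/load -> preprocess -> spectral ->
indices -> statistics and emits, under the output directory: grand-average
ERSP maps per condition with the cluster-masked difference map, frequency-
and time-domain energy curves, AMI/ERD electrode topographies with the
channel-space cluster test, the two summary tables, offline TBR curves,
and one machine-readable ``stats.json`` holding every number the figures
show.  ``run_online`` replays the cohort through the per-second TBR
monitor and runs the Bonferroni-corrected per-second tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_preprocess as iop
from . import spectral, stats
from .edf import read_edf
from .indices import (SubjectIndices, subject_ami, subject_tbr,
                      tbr_offline_series, tbr_online)
from .montage import electrode_adjacency, positions_2d
from .paradigm import (ALPHA_BAND, ATTENTION, CONDITIONS, INATTENTION, MI,
                       TRIAL_SPAN)
from .synthetic_data import SynthConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (YAML-serialisable)."""

    source: str = "synthetic"  # "synthetic" or a directory of EDF files
    synth: SynthConfig = field(default_factory=SynthConfig)
    fs_analysis: float = 200.0
    band: tuple[float, float] = (1.0, 30.0)
    erd_channel: str = "Cz"
    ami_electrode: str = "F4"
    tbr_channel: str = "Cz"
    alpha_band: tuple[float, float] = ALPHA_BAND
    mi_window: tuple[float, float] = MI
    wavelet: str = "db4"
    level: int = 8
    hop_s: float = 0.25
    n_perm: int = 1000
    alpha_form: float = 0.05
    alpha_cluster: float = 0.05
    bonferroni_alpha: float = 0.01
    seed: int = 0
    outdir: str = "miattn_out"
    figures: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["synth"]["channel_labels"] = list(d["synth"]["channel_labels"])
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        if "synth" in d:
            s = d["synth"]
            if "channel_labels" in s:
                s["channel_labels"] = tuple(s["channel_labels"])
            for key in ("theta_amp", "beta_amp", "tbr_target"):
                if s.get(key) is not None:
                    s[key] = dict(s[key])
            if "alpha_band" in s:
                s["alpha_band"] = tuple(s["alpha_band"])
            d["synth"] = SynthConfig(**s)
        for key in ("band", "alpha_band", "mi_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TopoMap:
    """Per-electrode scalars on projected 10/20 coordinates plus a grid."""

    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 2)
    values: np.ndarray  # (n,)
    condition: str = ""
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    grid_z: np.ndarray | None = None


def topography(values: dict, condition: str = "", resolution: int = 64
               ) -> TopoMap:
    """Attach per-electrode scalars to montage coordinates and interpolate.

    ``values`` maps electrode label -> scalar.  Raw values are always kept
    alongside the rendered grid (cubic interpolation inside the montage's
    convex hull).
    """
    from scipy.interpolate import griddata

    labels = tuple(values)
    coords = positions_2d(labels)  # raises on unknown electrodes
    vals = np.array([float(values[l]) for l in labels])
    pad = 0.05
    gx, gy = np.meshgrid(
        np.linspace(coords[:, 0].min() - pad, coords[:, 0].max() + pad, resolution),
        np.linspace(coords[:, 1].min() - pad, coords[:, 1].max() + pad, resolution))
    gz = griddata(coords, vals, (gx, gy), method="cubic")
    return TopoMap(labels, coords, vals, condition, gx, gy, gz)


def _load_cohort(config: RunConfig):
    if config.source == "synthetic":
        return generate_cohort(config.synth)
    src = Path(config.source)
    paths = sorted(src.glob("*.edf"))
    if not paths:
        raise FileNotFoundError(f"no EDF files under {src}")
    raws = []
    for p in paths:
        raw = read_edf(p)
        raw.subject = p.stem
        raws.append(raw)
    return raws, None


def preprocess_subject(raw, config: RunConfig) -> iop.TrialEpochs:
    """Standard chain: resample -> band-pass -> epoch -> baseline-correct."""
    raw = iop.resample(raw, config.fs_analysis)
    raw = iop.bandpass(raw, *config.band)
    epochs = iop.epoch(raw, TRIAL_SPAN)
    return iop.baseline_correct(epochs)


def _subject_seed(config: RunConfig, i: int) -> int:
    return (int(config.seed) * 100003 + i) % (2**31 - 1)


def run_offline(config: RunConfig) -> dict:
    """Execute the full offline analysis; returns the results dictionary.

    Deterministic under the config seeds: running twice writes
    byte-identical ``stats.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    raws, truth = _load_cohort(config)
    results: dict = {"n_subjects": len(raws), "seed": config.seed}

    maps = {c: [] for c in CONDITIONS}
    rows: list[SubjectIndices] = []
    tbr_curves = {c: [] for c in CONDITIONS}
    ami_by_electrode = {c: [] for c in CONDITIONS}
    erd_win = spectral.BandWindow(*config.alpha_band, *config.mi_window)

    for i, raw in enumerate(raws):
        epochs = preprocess_subject(raw, config)
        seed_i = _subject_seed(config, i)
        per_cond_erd = {}
        for cond in CONDITIONS:
            m = spectral.ersp(epochs, config.erd_channel, cond,
                              band=config.band, wavelet=config.wavelet,
                              level=config.level, hop_s=config.hop_s)
            maps[cond].append(m)
            per_cond_erd[cond] = spectral.erd(m, erd_win)
        ami_res = subject_ami(epochs, config.ami_electrode, seed=seed_i)
        tbr_res = subject_tbr(epochs, config.tbr_channel,
                              wavelet=config.wavelet, level=config.level)
        series = tbr_offline_series(epochs, config.tbr_channel,
                                    wavelet=config.wavelet, level=config.level)
        for cond in CONDITIONS:
            rows.append(SubjectIndices(
                subject=raw.subject or f"S{i + 1}", condition=cond,
                erd=per_cond_erd[cond], ami=ami_res[cond],
                tbr=tbr_res[cond]))
            tbr_curves[cond].append(series[cond])
        # per-electrode AMI and ERD for the topographies / channel test
        el_ami = {}
        for ch in epochs.channel_labels:
            el_ami[ch] = subject_ami(epochs, ch, seed=seed_i)
        for cond in CONDITIONS:
            ami_by_electrode[cond].append(
                {ch: el_ami[ch][cond] for ch in epochs.channel_labels})
        logger.info("subject %d/%d analysed", i + 1, len(raws))

    channel_labels = raws[0].channel_labels

    # grand averages and the TF cluster test at the ERD channel
    grand = {c: np.mean([m.values for m in maps[c]], axis=0)
             for c in CONDITIONS}
    tf_result = stats.cluster_perm_tf(
        maps[ATTENTION], maps[INATTENTION], n_perm=config.n_perm,
        alpha_form=config.alpha_form, alpha_cluster=config.alpha_cluster,
        seed=config.seed)
    results["tf_clusters"] = json.loads(tf_result.to_json())
    results["n_significant_tf_clusters"] = len(tf_result.significant)

    # energy curves
    curves = {}
    for cond in CONDITIONS:
        curves[cond] = {
            "frequency": spectral.energy_curve(maps[cond], "over_time",
                                               band=config.alpha_band),
            "time": spectral.energy_curve(maps[cond], "over_frequency",
                                          band=config.alpha_band),
        }

    # channel-space cluster test on AMI
    adjacency = electrode_adjacency(channel_labels)
    val = {c: np.array([[s[ch] for ch in channel_labels]
                        for s in ami_by_electrode[c]]) for c in CONDITIONS}
    ch_result = stats.cluster_perm_channels(
        val[ATTENTION], val[INATTENTION], adjacency, n_perm=config.n_perm,
        alpha_form=config.alpha_form, alpha_cluster=config.alpha_cluster,
        seed=config.seed, labels=channel_labels)
    results["channel_clusters"] = json.loads(ch_result.to_json())

    # summary tables and paired comparisons
    table_ami = stats.build_summary_table(
        [r for r in rows], metrics=("erd", "ami"))
    table_tbr = stats.build_summary_table(
        [r for r in rows], metrics=("erd", "tbr"))
    table_ami.to_csv(outdir / "table_erd_ami.tsv", sep="\t")
    table_tbr.to_csv(outdir / "table_erd_tbr.tsv", sep="\t")

    by_cond = {c: [r for r in rows if r.condition == c] for c in CONDITIONS}
    for metric in ("erd", "ami", "tbr"):
        a = [getattr(r, metric) for r in by_cond[ATTENTION]]
        b = [getattr(r, metric) for r in by_cond[INATTENTION]]
        results[f"{metric}_mean"] = {
            ATTENTION: float(np.mean(a)), INATTENTION: float(np.mean(b))}
        if len(a) >= 2:
            try:
                t, df, p = stats.paired_t(a, b)
                results[f"{metric}_paired_t"] = {"t": t, "df": df, "p": p}
            except ValueError as err:
                results[f"{metric}_paired_t"] = {"note": str(err)}
        if len(a) >= 3:
            w_a, p_a = stats.normality_check(np.array(a) - np.array(b))
            results[f"{metric}_shapiro_diff"] = {"W": w_a, "p": p_a}

    results["tbr_series"] = {
        c: {"times": tbr_curves[c][0].times.tolist(),
            "mean": np.mean([s.values for s in tbr_curves[c]], axis=0).tolist()}
        for c in CONDITIONS}
    results["energy_curves"] = {
        c: {k: {"axis": v.axis.tolist(), "values": v.values.tolist()}
            for k, v in curves[c].items()} for c in CONDITIONS}

    with open(outdir / "stats.json", "w") as f:
        json.dump(results, f, indent=2, sort_keys=True)

    if config.figures:
        _offline_figures(outdir, config, maps, grand, tf_result, curves,
                         tbr_curves, ami_by_electrode, channel_labels)
    return results


def run_online(config: RunConfig) -> dict:
    """Simulated-online run: per-second TBR on 1-s buffers, per-second tests."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raws, _ = _load_cohort(config)
    fs = config.fs_analysis
    n_sam = int(round(fs))
    span = (1.0, 5.0)
    per_subject = {c: [] for c in CONDITIONS}
    for raw in raws:
        epochs = preprocess_subject(raw, config)
        ci = epochs.channel_index(config.tbr_channel)
        for cond in CONDITIONS:
            sub = epochs.select(cond)
            vals = []
            for trial in sub.data[:, ci, :]:
                i0 = int(round((span[0] - epochs.times[0]) * fs))
                n_buf = int(span[1] - span[0])
                buffers = [trial[i0 + k * n_sam: i0 + (k + 1) * n_sam]
                           for k in range(n_buf)]
                series = tbr_online(buffers, fs, wavelet=config.wavelet,
                                    level=config.level, t0=span[0])
                vals.append(series.values)
            per_subject[cond].append(np.mean(vals, axis=0))
    a = np.array(per_subject[ATTENTION])
    b = np.array(per_subject[INATTENTION])
    stamps = span[0] + 1.0 + np.arange(a.shape[1])
    report: dict = {"times": stamps.tolist(),
                    "tbr_mean": {ATTENTION: a.mean(axis=0).tolist(),
                                 INATTENTION: b.mean(axis=0).tolist()}}
    if a.shape[0] >= 2:
        table = stats.bonferroni_per_second(a, b, times=stamps,
                                            alpha_family=config.bonferroni_alpha)
        table.to_csv(outdir / "online_tbr_tests.tsv", sep="\t", index=False)
        report["per_second"] = table.to_dict(orient="records")
    else:
        report["per_second"] = []
        report["note"] = "fewer than two subjects: per-second t-tests skipped"
    with open(outdir / "online_stats.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# figures (every figure's numbers also live in stats.json / the TSVs)
# ---------------------------------------------------------------------------

def _offline_figures(outdir, config, maps, grand, tf_result, curves,
                     tbr_curves, ami_by_electrode, channel_labels):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = maps[ATTENTION][0]
    extent = [ref.times[0], ref.times[-1], ref.freqs[0], ref.freqs[-1]]
    fig, axes = plt.subplots(1, 3, figsize=(14, 4), constrained_layout=True)
    for ax, cond in zip(axes, CONDITIONS):
        im = ax.imshow(grand[cond], aspect="auto", origin="lower",
                       extent=extent, cmap="RdBu_r", vmin=-3, vmax=3)
        ax.set(title=f"grand ERSP: {cond}", xlabel="time (s)",
               ylabel="frequency (Hz)")
    im = axes[2].imshow(tf_result.sig_mask, aspect="auto", origin="lower",
                        extent=extent, cmap="RdBu_r")
    axes[2].set(title="significant cluster t (A - I)", xlabel="time (s)")
    fig.colorbar(im, ax=axes, shrink=0.8, label="dB / t")
    fig.savefig(outdir / "ersp_maps.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), constrained_layout=True)
    for cond in CONDITIONS:
        axes[0].plot(curves[cond]["frequency"].axis,
                     curves[cond]["frequency"].values, label=cond)
        axes[1].plot(curves[cond]["time"].axis,
                     curves[cond]["time"].values, label=cond)
    axes[0].set(xlabel="frequency (Hz)", ylabel="energy (dB)")
    axes[1].set(xlabel="time (s)", ylabel="alpha energy (dB)")
    for ax in axes:
        ax.legend()
    fig.savefig(outdir / "energy_curves.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), constrained_layout=True)
    for ax, cond in zip(axes, CONDITIONS):
        mean_ami = {ch: float(np.mean([s[ch] for s in ami_by_electrode[cond]]))
                    for ch in channel_labels}
        topo = topography(mean_ami, cond)
        pc = ax.pcolormesh(topo.grid_x, topo.grid_y, topo.grid_z,
                           cmap="RdBu_r", shading="auto")
        ax.scatter(topo.coords[:, 0], topo.coords[:, 1], s=8, c="k")
        ax.set(title=f"AMI: {cond}", aspect="equal")
        fig.colorbar(pc, ax=ax, shrink=0.8)
    fig.savefig(outdir / "ami_topography.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    for cond in CONDITIONS:
        mean_curve = np.mean([s.values for s in tbr_curves[cond]], axis=0)
        ax.plot(tbr_curves[cond][0].times, mean_curve, marker="o", label=cond)
    ax.set(xlabel="time (s)", ylabel="TBR")
    ax.legend()
    fig.savefig(outdir / "tbr_curves.png", dpi=120)
    plt.close(fig)
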