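# miattn

Attention-state analysis of lower-limb motor-imagery (MI) EEG: event-related
desynchronization (ERD) from wavelet-packet ERSP maps, the alpha modulation
index (AMI), real-time theta/beta-ratio (TBR) attention monitoring, and
cluster-based permutation statistics — with a synthetic-cohort generator
that provides exact ground truth for every stage.

## The problem

During motor imagery, focused attention deepens the suppression of the
sensorimotor alpha rhythm (8–13 Hz) — the ERD — and that suppression is what
MI-based brain–computer interfaces decode.  This package implements the
analysis chain for a key-press paradigm in which each 9 s trial runs
Ready (−2..−1 s), Start (−1..0 s, the baseline), Select (0..1 s, an arrow
cue answered by a key press), MI (1..5 s) and Rest (5..7 s); trials are
labeled *Attention* or *Inattention* by key-press correctness.  It targets
researchers who need a tested, reproducible pipeline for 32-channel 10/20
recordings (or simulations of them) rather than one-off scripts.

## The quantities

With `K(f,t,k)` the spectral estimate of trial `k` (short-time wavelet
packets, `db4`, level 8, 0.39 Hz bins at 200 Hz):

- **ERSP**  `ERSP(f,t) = (1/N) Σₖ |K(f,t,k)|²`, in dB relative to the
  per-frequency mean power of the −1..0 s baseline;
- **ERD**  the mean of the ERSP dB values over the alpha band × MI window
  (an injected alpha-amplitude suppression of depth *d* appears as
  `20·log₁₀(1−d)` dB);
- **AMI**  `(α_AR − α_AW)/(α_AR + α_AW)` from FFT alpha power at F4 for
  correct- vs incorrect-response trials, class-balanced first;
- **TBR**  `E_θ / E_β` from wavelet-packet band energies on 1 s windows —
  computable once per second online, with no look-ahead;
- **Cluster statistics**  paired-t cluster masses over adjacent
  time–frequency bins or adjacent electrodes, ranked against a
  sign-flip permutation null of maximum |mass|.

## Worked example

```python
import numpy as np
from miattn import SynthConfig, generate_subject, ersp, erd, subject_ami, subject_tbr
from miattn.pipeline import RunConfig, preprocess_subject

cfg = SynthConfig(n_subjects=1, seed=3)          # study-calibrated defaults
raw, truth = generate_subject(cfg, 0)            # 4 sets x 20 trials, 32 ch
epochs = preprocess_subject(raw, RunConfig())    # 200 Hz, 1-30 Hz, epoched

m = ersp(epochs, "Cz", "Attention")              # dB re -1..0 s baseline
print(f"Attention alpha ERD at Cz: {erd(m):.2f} dB over {m.n_trials} trials")
print(f"Inattention alpha ERD at Cz: {erd(ersp(epochs, 'Cz', 'Inattention')):.2f} dB")
ami_res = subject_ami(epochs, "F4", seed=0)
print(f"AMI at F4: {ami_res['Attention']:.4f}")
tbr = subject_tbr(epochs)
print(f"TBR at Cz: {tbr['Attention']:.3f} (Attention) vs {tbr['Inattention']:.3f} (Inattention)")
```

prints

```
Attention alpha ERD at Cz: -1.62 dB over 62 trials
Inattention alpha ERD at Cz: -1.24 dB
AMI at F4: -0.1353
TBR at Cz: 2.421 (Attention) vs 2.460 (Inattention)
```

The Attention ERD is more negative than the Inattention ERD (stronger alpha
suppression under attention), the negative AMI says this subject's F4 alpha
power is lower on correct-response trials, and the Attention TBR sits below
the Inattention TBR — the direction the real-time monitor exploits.  One
subject is noisy; group-level contrasts come from `pipeline.run_offline`,
which also writes the summary tables, cluster tests, energy curves and
topographies (plus every figure's numbers as TSV/JSON).

A full cohort from the shell:

```sh
miattn analyze --seed 1 --outdir out/        # offline pipeline on synthetic cohort
miattn online  --seed 1 --outdir out/        # per-second TBR monitor + tests
miattn simulate --seed 1 --outdir cohort/    # export EDF files + truth table
miattn analyze --source cohort/ --outdir out2/   # same pipeline from EDF
```

## Layout

- `miattn.synthetic_data` — cohort generator (the study conditions are the defaults)
- `miattn.io_preprocess`, `miattn.edf` — EDF/HDF5 I/O, resampling, filtering, epoching, balancing
- `miattn.spectral` — wavelet-packet spectrograms, ERSP/ERD, energy curves, FFT band power
- `miattn.indices` — AMI, TBR, offline series and the online per-second monitor
- `miattn.stats` — paired tests, correlations, summary tables, cluster permutation tests
- `miattn.montage` — 10/20 positions and electrode adjacency
- `miattn.pipeline`, `miattn.cli` — end-to-end runs, figures, the `miattn` command
- `miattn.validation` — ground-truth experiments used by the acceptance machinery

See `docs/methods.md` for the model, parameter and calibration details.
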