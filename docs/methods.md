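# Methods

## Paradigm and preprocessing

Each trial follows a fixed 9 s timeline relative to the Select cue (t = 0):
Ready [−2,−1), Start [−1,0) — the spectral baseline — Select [0,1), motor
imagery [1,5), Rest [5,7).  Trials are labeled Attention/Inattention by
key-press correctness; a missing response never defaults to Inattention —
the trial is flagged invalid and dropped.

Raw recordings (nominally 1000 Hz, 32 channels, 10/20 labels, microvolts)
are polyphase-resampled to 200 Hz, band-passed 1–30 Hz with a 4th-order
Butterworth applied forward–backward (zero phase, so ERD latencies are not
shifted), epoched to [−2,7) s and baseline-corrected by subtracting the
per-trial, per-channel mean of [−1,0) s.  Trials whose window exceeds the
record are dropped with a logged count, never imputed.  An optional
artifact-removal hook accepts an external ICA-based backend; it is a
pass-through by default and is not exercised by the tests.

## Spectral estimation

Spectral estimates use a short-time wavelet-packet transform: sliding
windows of 2⁸ = 256 samples (1.28 s at 200 Hz, hop 0.25 s) are decomposed
to level 8 with an orthogonal wavelet (`db4` default, `periodization`
mode), giving exactly one coefficient per terminal node — a 256-bin
spectrum with 0.39 Hz resolution and exact energy conservation (Parseval
holds to machine precision, including for zero-padded windows).  A single
whole-epoch decomposition was rejected because its 1.28 s coefficient
spacing cannot resolve the 1 s baseline.

ERSP averages per-trial window power over trials first, then converts to
dB against the per-frequency mean power of the baseline bins.  Two
window-selection rules coexist deliberately:

- *baseline* bins are selected by window **center** in [−1,0) — no 1.28 s
  window fits wholly inside a 1 s baseline, and the slight overhang is
  harmless whenever pre-cue activity is stationary (true of the generator;
  a caveat for real data with early anticipatory ERD);
- *task* windows (ERD, energy-curve time ranges) require **full support**
  inside the requested interval, which removes transition smearing and
  makes the injected-depth closed form `20·log₁₀(1−d)` exact.

ERD is the plain mean of the dB map over the band window (the number of
bins in the window is the normalizer).  Frequency rows are selected by bin
center in half-open bands [f1, f2); alpha is 8–13 Hz, theta 4–8 Hz, beta
13–30 Hz, all configurable.

`db4` is kept as the default mother wavelet (it is the method's stated
parameter and its short filters are cheap), with one documented
consequence: level-8 `db4` packets alias roughly a fifth of a mid-alpha
tone's energy into neighbouring bands (measured 78 % in-band capture for a
10 Hz tone; `db16` reaches 95 %).  Ratio quantities — ERSP in dB, ERD,
TBR — are unaffected because the capture factor cancels between numerator
and reference; absolute band-energy readings are not, so every entry point
accepts a `wavelet` argument.

AMI uses FFT band power instead: the periodogram of the [1,5) s segment,
summed over bins in [8,13) Hz and normalized so the full-spectrum sum is
the segment's mean-square power.  The correct/incorrect groups are
equalized first by subsampling the majority class without replacement
(seeded, deterministic); per-group power is the mean over that group's
trials.  Because the per-condition columns of the reference tables pair
with a single right/wrong contrast, the Inattention column reports the
antisymmetric orientation of the Attention value.

TBR divides theta by beta wavelet-packet band energy on 1 s windows.
A 200-sample buffer cannot carry a level-8 decomposition, so windows are
zero-padded to 256 samples; the transform stays orthonormal, hence scale
invariance and exact online/offline agreement hold bit-for-bit (both paths
share one function).  The padding makes a stationary tone's per-window
energy mildly phase-dependent, which averages out over trials with random
phases.  Online mode consumes strictly causal non-overlapping 1 s buffers,
emits one value per buffer, and skips malformed buffers with a logged gap.

## Statistics

Paired t-tests (two-sided), Shapiro–Wilk normality checks and Pearson
correlations (p from the exact t transform, n−2 df) delegate to scipy.
Summary tables report the mean and the *population* standard deviation
(divisor N), the convention that reproduces the reference tables' "SDT"
rows.

The cluster-based permutation test controls family-wise error for
mass-univariate paired comparisons.  Bins with two-sided p < 0.05 under
the bin-wise paired t form clusters — 4-connectivity (no diagonals) on the
time–frequency grid, graph adjacency in electrode space — separately per
t-sign, scored by mass (sum of t-values).  The null distribution of
maximum |mass| comes from random per-subject sign flips of the condition
differences (the within-subject exchangeability under "no effect"), and
corrected p-values use the (1 + count)/(n_perm + 1) estimator.  Zero-
variance, zero-mean difference bins are defined as non-suprathreshold.
Observed cluster masses and memberships agree exactly with an established
independent implementation (checked in the tests).  Electrode adjacency is
the Delaunay triangulation of azimuthal-equidistant-projected standard
10/20 positions with edges above 1.8× the median length pruned, emitted as
an inspectable edge list.

Per-second online comparisons use paired t-tests at each second with
Bonferroni correction (raw p × number of seconds, capped at 1) against a
family alpha of 0.01.

## The synthetic cohort

The generator emulates 14 subjects × 4 sets × 20 trials.  Per channel it
sums 1/f^1 background noise (RMS 2 µV) with, at Cz, a band-limited alpha
process, a theta tone and a beta tone, and at F4 a second alpha process.
Labels are Bernoulli draws (p = 0.7 Attention) with the key response set
to match, so the class-imbalance path of the AMI estimator is always
exercised.

*Alpha.*  The alpha rhythm is unit-RMS Gaussian noise band-passed to
7.25–13.75 Hz — deliberately 0.75 Hz wider than the 8–13 Hz analysis band
so the filter rolloff falls outside the measured rows (a pure tone would
fill only ~5 of the 13 alpha rows and dilute the band-mean ERD).  Its RMS
is set `snr_db` (default 20 dB) above the realized 8–13 Hz noise floor,
and its amplitude is multiplied by (1 − depth) during [1,5) s; the default
Attention depth 0.185 injects the reference cohort's −1.77 dB group ERD
via 20·log₁₀(1−d), the Inattention default is null.

*Theta/beta tones.*  The theta tone sits at 5.5 Hz: probe measurements of
the db4 packet bank showed a 6 Hz tone aliases 3.9 % of its energy into
the alpha rows (≈ +0.5 dB ERD bias at the solved amplitudes) while 5.5 Hz
aliases 0.5 %.  The beta tone is 20 Hz at 6 µV.  Because db4 aliasing also
sends 10–15 % of alpha power into the 13–16 Hz beta rows, a fixed theta
amplitude would couple the condition-dependent ERD into TBR with the wrong
sign and swamp the ~1 % target decrement.  The generator therefore treats
the per-condition TBR targets (2.5511 Attention, 2.5803 Inattention, the
reference group means) as *realized* band-energy ratios and solves the
theta amplitude per condition by a short fixed-point iteration against
probe-measured leakage of the alpha process, the tones and the noise.
Explicit `theta_amp` values bypass the solve.  The realized trial-mean TBR
still sits ≈ 0.1 above target — the mean of per-window ratios exceeds the
ratio of mean energies (Jensen) — but the ordering and the paired contrast
are on target.

*Subject heterogeneity.*  All subject effects load on one latent
attentional-engagement factor z: the Attention depth (SD 0.10, loading
0.8), the F4 gains (0.98/1.02, SD 0.03, loadings ∓0.8), and a
multiplicative TBR gain (SD 0.06, loading −0.75).  This reproduces the
reference cohort's strong between-subject ERD–AMI and ERD–TBR correlations
and its sign flips; the loadings were fixed once from the tables' SD rows.

*What it does not emulate.*  No ocular or muscle artifacts (the ICA stage
is out of scope), no volume conduction or forward-model topography (only
Cz/F4 carry signal, other channels are noise), no trial-to-trial amplitude
drift or fatigue, and no behavioral reaction-time structure.  Passing
tests therefore certify the estimators and statistics against known
spectral ground truth, not robustness to real-world artifacts.

*Determinism.*  Every draw derives from `SeedSequence((seed, subject))`;
identical configs are bit-identical, and the full pipeline writes
byte-identical JSON under a fixed seed.

## Validation experiments

`miattn.validation` re-runs the chain against ground truth:

- **ERD recovery** — depth 0.4 for all 14 subjects (subject SD 0), full
  generate→preprocess→ERSP→ERD pipeline, compared to −4.44 dB.  The
  experiment uses 25 dB SNR: the closed form is exact in the high-SNR
  limit, and residual noise/leakage dilution at 20 dB shifts the estimate
  by ≈ +0.3 dB (still within a ±0.5 dB band, but not centered).
- **FWER calibration** — 200 null cohorts (n = 14, 20×20 maps, 500
  permutations each); the fraction with any significant cluster estimates
  the family-wise error at α = 0.05.
- **Block recovery** — a strong suppressed block must return exactly one
  significant cluster covering ≥ 80 % of its bins with ≤ 5 % spillover.
- **Channel localization** — a per-subject effect confined to the adjacent
  pair {F4, FC4} (all other electrodes carry identical paired values, so
  their differences are exactly zero) must be recovered as precisely that
  cluster; non-adjacent injections must never merge.  With i.i.d. noise at
  every electrode this exactness would be unattainable — the p < 0.05
  forming threshold admits each neighbour with 5 % probability regardless
  of effect size — which is why the fixture pins non-target differences
  to zero.
- **Online/offline contract** — replaying epochs as 1 s buffers must
  reproduce the offline non-overlapping series exactly (max |Δ| = 0).

Problem sizes (14 subjects, 20×20 calibration grids, 200 cohorts, 50
localization runs) were chosen as the smallest that leave the Monte-Carlo
error well inside the decision margins.

## Known limitations

- The printed group t-statistic for offline TBR in the reference material
  is not recoverable from its own per-subject columns (they give
  t(13) ≈ −1.50); the package always reports what the data give, and the
  discrepancy is asserted, not reconciled.  Likewise the two reference
  tables disagree on four subjects' Attention ERD values and one printed
  correlation; each table is used as printed.
- db4's cross-band aliasing is inherent to the transform choice; analyses
  needing sharp band separation should pass `wavelet="db16"`.
- The AMI per-condition reporting convention (antisymmetric orientations)
  is one reading of an under-specified table layout; the underlying
  contrast is a single number per subject.
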