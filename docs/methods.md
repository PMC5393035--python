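# Methods

This note documents the models, estimators and numerical choices behind
`wristssr`, and what the synthetic-data experiments do and do not establish.

## Stimulus model

The disturbance is a periodic sum of cosines on a common grid,
`d(t) = Σ_i a_i cos(2π f_i t + φ_i)`, with the 14 study frequencies
(0.8–19.2 Hz, all multiples of 1/1.25 s). The published design fixes the
frequency list, the period, the 0.02 rad RMS excursion, the −20 dB/decade
amplitude roll-off above 4 Hz, and the left-hand sign flip, but not the
absolute line amplitudes or the phase distribution. Choices made here:

- **Amplitude shape**: flat for f ≤ 4 Hz, `a ∝ 4/f` above — the simplest
  shape consistent with "highest amplitudes below the wrist's natural
  frequency" plus the stated roll-off. A single global rescale then sets
  the single-period RMS to exactly 0.02 rad.
- **Phases**: i.i.d. uniform on [0, 2π) from a seeded generator, recorded in
  the spec for reproducibility. No crest-factor optimization is performed.
- **Left-hand "flip"** is waveform negation (mirrored flexion/extension).

Rendering evaluates one period on the sample grid and tiles it, so
periodicity is exact to the bit and all energy falls exactly on FFT bins
whenever `sample_rate × 1.25 s` is an integer (true for 2048 Hz and for the
256 Hz used in the scaled experiments; incompatible rates are rejected).

## Outcome metrics

Per electrode, over a stack of `P` retained periods of `N` samples:
SSR `x̂(k)` (mean over periods), SSR power `Ê = Σ_k x̂²` (summed over
samples, so `N` must match between compared tasks — enforced), noise
variance `Σ_k var_p` with the unbiased `P−1` divisor, and their ratio, the
SNR. Identical periods give a zero denominator and are reported as infinite
SNR, not an exception. Under pure noise `E[Ê] ≈ Nσ²/P` while the
denominator ≈ `Nσ²`, so the null SNR floor is ≈ 1/P; estimators are
validated against this closed form.

`ΔE` compares SSR power between tasks; a non-positive passive power leaves
it undefined (reported missing), mirroring the interpretation problem when
no passive response exists. Hemisphere-level ΔE uses set-mean powers
(mean of `Ê` over an electrode set) rather than the mean of per-electrode
percentages, which is unstable when single-electrode passive powers
approach zero.

The laterality index contrasts mean SNR over two mirror-symmetric
15-electrode sensorimotor sets (odd = left hemisphere). "Contralateral"
follows the crossed somatosensory pathways: right-wrist stimulation →
odd-numbered set. Electrodes excluded as bad are dropped together with
their mirrors so the sets stay symmetric. Both set means zero → LI
undefined. For group-level topographies, left-hand recordings are flipped
electrode-wise (C3↔C4, midline fixed) *before* averaging.

## Preprocessing

4th-order Butterworth band-pass 0.8–120 Hz plus band-stops at 50 ± 1 and
100 ± 1 Hz (the "narrow bands" are unspecified in the design; ±1 Hz is the
standard line-noise width at this trial length), applied forward-backward
(`sosfiltfilt`) per trial for zero phase. Filtering per trial respects the
recorded structure; the edge ringing this causes falls largely in the two
leading periods that are discarded as motor transients anyway. Bad channels
are taken from an explicit list (hardware impedance flags are not available
for synthetic or replayed data) or auto-detected as robust outliers in
broadband log-variance (> 5 scaled MADs from the median). Common-average
re-referencing subtracts the instantaneous mean of retained channels.

Period bookkeeping: 12.5 s trials → ten 1.25 s periods, first two
discarded (20 trials → 160 periods). Active-task periods are kept iff the
period-mean torque lies in the **closed** interval `target·[0.5, 1.5]`
(boundary handling is frozen and unit-tested); an active task with fewer
than 80 surviving periods is excluded.

## ICA artifact handling

One decomposition is computed over both tasks combined, on centred,
PCA-whitened data reduced to numerical rank (the common average removes one
dimension). Backends: FastICA (default — fast, seeded, deterministic) and
extended Infomax via mne (the algorithm family of the original analysis);
the scientific content is in the component classification, not the unmixing
flavor. Heuristics, with thresholds as config keys since no numeric values
are published: *muscle* — positive slope of log-power vs log-frequency over
20–120 Hz (capped at 0.45·fs); *single-electrode* — one electrode carrying
> 80% of topography energy; *eye* — > 60% of topography energy on the
frontal-pole set {Fp1, Fpz, Fp2, AF7…AF8} and > 50% of source power below
5 Hz. Rules are applied in the order single-electrode → muscle → eye.
Cleaning projects the remaining components back; it is a linear projection,
hence idempotent, and preserves period-locked response power when only
artifact components are rejected (checked against simulator ground truth).

## Synthetic data

The generator emulates the study's recordings, not any particular dataset:

- **Response**: one period of a waveform with 70% of its power at the 14
  stimulated lines and 30% at their even harmonics (the physiological
  response is nonlinear but periodic), template RMS 8 µV at unit gain,
  multiplied by a per-electrode gain topography — a Gaussian in the
  azimuthal montage plane (σ = 0.30 rad ≈ 3 cm, a focal sensorimotor patch)
  peaked between C3/CP3 for right-wrist stimulation, mirrored for left,
  with a 10% ipsilateral leak by default.
- **Background**: per-channel 1/f-shaped noise (amplitude ∝ f^−½ above
  1 Hz) with a 10 Hz alpha bump, 10 µV RMS, mixed through a smooth spatial
  covariance from electrode distances; uncorrelated with the stimulus by
  construction. The template/background ratio was chosen by design power
  analysis so that group structure and the active/passive power ratio are
  recoverable at the study's period counts while severe-group responses
  (gain 0.05) stay at the SNR noise floor.
- **Group gains** (control 1.0, none 0.9, mild 0.6, severe 0.05) and the
  mild group's active/passive power ratio 0.5 are free calibration
  constants reproducing the qualitative group ordering; the study reports
  no quantitative per-group SNR, so these are config, not claims.
- **Artifacts**: blinks (sparse Hanning bumps, broad forehead topography)
  and bursty scalp-EMG (spectrum rising with f, envelope-modulated,
  temporal-chain topography). Torque traces have a configurable fraction
  of periods violating the ±50% criterion; EMG is quiescent in the passive
  and elevated in the active task.
- **Cohort**: per-participant paired sessions with group-dependent gains
  (multiplicative log-normal jitter, σ = 0.1); the SMT lesion volume is a
  stated monotone map `v = v_max(1 − g/g_max) + ε`, so the regression stage
  has recoverable structure and, at ε = 0, Spearman ρ(gain, volume) = −1
  exactly.

What passing tests show: the estimators are unbiased/calibrated under this
generative model. What they do not show: robustness to real-EEG features
the generator omits — non-stationary background, volume-conduction from a
biophysical head model, realistic EMG spectra, electrode drift.

## Statistics and regression

ANOVA is the classical equal-variance F (no correction is specified in the
design); groups with < 2 observations are excluded with a warning; an
all-equal input reports F = 0, p = 1 by convention. Tukey HSD pairs are
computed only when the omnibus test is significant (α = 0.05, two-tailed
throughout). Wilcoxon signed-rank uses the exact null for n ≤ 25 and the
continuity-corrected normal approximation above. Spearman is tie-corrected.

LASSO: predictors standardized; λ selected by minimum cross-validated MSE
on a 30-point log grid from the data-derived λ_max down 3 decades; ten
folds stratified by target quantile with seeded tie-breaks; final refit on
all data at the selected λ. VAF = 100·(1 − var(y−ŷ)/var(y)) is reported
both in-sample (final refit) and cross-validated (pooled out-of-fold
predictions), since the original definition is not stated. Permutation
significance re-runs the *entire* selection-and-refit procedure on each
permuted target and uses the add-one estimator
`p = (1 + #{VAF_perm ≥ VAF_obs})/(1 + n_perm)`, which cannot return zero.
The compared statistic is the cross-validated VAF: under a null target the
selected penalty usually shrinks every coefficient away, making the
in-sample VAF exactly zero for most permutations — the resulting ties
destroy the uniformity of the p-value, whereas the out-of-fold VAF is
continuous and yields a calibrated test.

## Problem sizes and determinism

Calibration experiments run at 256 Hz (320 samples per 1.25 s period — the
period grid stays exact) with the full 64-channel montage: null-SNR and
recovery experiments use the study's 160-period sessions over 20 seeds;
type-I calibrations use 1000 null replicates per test; permutation-p
uniformity uses 200 replicates × 100 permutations; the demonstration
pipeline uses a 4+4+4+4 cohort, 12 trials per task and 100 permutations.
Every random operation draws from a seed derived from one root seed
(`numpy` `SeedSequence`), so a fixed config reproduces byte-identical
outputs; the pipeline manifest records the config hash and all derived
seeds.

## Known limitations

- The packaged clinical table is transcribed from a printed source whose
  group-size footnote (6/13/11) disagrees with its own per-row labels
  (7/12/11); the per-row data are internally consistent with the
  classification rule, the stated FMA-UE sort, and the cohort demographics,
  so the rows are taken as authoritative and the derived counts are 7/12/11.
- EDF export is not provided; sessions are serialized as NPZ + JSON/CSV.
- The ICA heuristics use fixed thresholds, not learned classifiers, and are
  validated only on the simulator's stereotyped artifacts.
- MRI lesion segmentation is out of scope: lesion volume enters as a given
  scalar per participant.
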