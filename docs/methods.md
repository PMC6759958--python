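# Methods

This note records the models implemented in `phtremor`, the parameter
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that a user
extending or auditing the package needs to know.

## Experimental design encoded in the defaults

`ExperimentConfig` defaults describe the session design the package
analyses: fMRI scans of 242 volumes at TR 2 s (484 s total) with an
intravenous injection initiated at t = 234 s over 40 s; seven sessions
per animal — three drug fMRI scans interleaved with three behavioural
accelerometer sessions, 72 h apart, plus a saline-control scan run
immediately after the final drug scan (interval 0 h). Injections are
numbered 1–6 across the alternating schedule; the saline scan carries
no injection. Behavioural sessions record 100 Hz accelerometry over a
30-min baseline and a 2-h post-injection period (both durations are
scalable for quick experiments; analyses that rely on the 30-min
baseline normalisation assume at least three 10-min baseline windows).

## Synthetic-data generator

The generator exists because the analyses need data with known ground
truth. Each fMRI voxel series is

    y(t) = b · [ 1 + a_R/100 · x_L(t) + g_c/100 · z(t) ] + roi-level
           fluctuations + white noise,

where b = 1000 is the baseline level, a_R the percent-signal-change
amplitude of the voxel's ROI, x_L the HRF-convolved response block
(length L = 25 s by default), g_c the artifact gain of the voxel's
tissue class and z(t) = (HR(t) − HR₀)/HR₀ the relative heart-rate
deviation resampled to volume onsets.

Defaults and their rationale:

- **ROI amplitudes** (% PSC): ION 1.0, cerebellum 1.0, DCN 0.8,
  thalamus 0.6, SMC 0.3, limbic 0.2, visual 0.3 — the olivo-cerebellar
  nodes respond most strongly; 1% is a typical block-design effect size
  at 3 T.
- **Heart rate**: baseline 120 bpm (the monitored sedated baseline).
  The drop amplitude is a free parameter — the bradycardia is reported
  only graphically in the literature this design follows — with default
  40 bpm, nadir at 600 s post-injection ("minimum around 10 min") and
  recovery time-constant 600 s. The trajectory is
  HR₀ − D·g(t′)/g(t_nadir) with
  g(t′) = (1 − e^(−t′/τ_rise)) e^(−max(0, t′−t_nadir)/τ_rec); the
  normalisation by g(t_nadir) makes the configured drop amplitude exact
  at the nadir.
- **Artifact gains**: gray 3, white 2, CSF 1 (% of baseline per unit
  relative HR deviation; all voxels default to gray). With the default
  bradycardia this produces a ≈1% downward drift by scan end —
  comparable to the response amplitude, i.e. an artifact that genuinely
  must be removed.
- **Noise**: white Gaussian per voxel, sd 0.5% of baseline — a
  realistic thermal-noise level for 3 T EPI at this voxel size.
  Temporal autocorrelation is deliberately omitted (see Limitations).
- **ROI-level fluctuations**: each named ROI receives a shared white
  fluctuation (sd 0.25%) throughout the scan, so ROI-mean series have
  realistic variance; after the injection, additional shared signals
  couple cerebellum–thalamus (sd 0.35%) and cerebellum–DCN (sd 0.30%),
  which is what the connectivity analysis is designed to detect.
- **Accelerometer**: broadband sub-10-Hz motion (4th-order Butterworth
  filtered white noise, unit sd) plus a white sensor floor (sd 0.05)
  and, post-injection, a 13 Hz tremor sinusoid (amplitude 2.0) whose
  envelope rises with τ = 60 s and decays with τ = 2400 s ("initiated
  immediately, maintained over an hour").
- **Tolerance**: amplitudes, tremor amplitude and coupling strengths
  all scale by decay^(injection − 1) with decay = 0.7, giving a clear
  but not degenerate decline over six injections. Per-animal severity
  (lognormal, log-sd 0.15) multiplies both activation and tremor, so
  the beta-vs-tremor regression has a real effect to find.

Randomness is hierarchical: one root `SeedSequence` spawns per-animal
sequences, which spawn per-session streams; identical (config, seed)
pairs are bit-identical.

**What the generator does not emulate**: scanner physics (k-space, EPI
distortion), motion, real pig-brain geometry (ROIs are labelled
cuboids on a 24×24×16 grid with 1.7×1.7×2.4 mm voxels),
autocorrelated physiological noise, multi-axis accelerometry, or
tremor frequency drift. Passing recovery tests therefore demonstrates
the correctness of the analysis code and its statistical calibration
under the stated model — not robustness to preprocessing failures that
real scanner data can exhibit upstream of this pipeline.

## Artifact correction and the activation GLM

The nuisance design is [intercept, linear drift, HR]; the HR regressor
is linearly interpolated at volume onsets, mean-centred, scaled to unit
sd, and used unlagged by default (an integer-volume lag is exposed,
since the BOLD drift can trail the heart-rate change slightly).
Whether to mean-centre or convolve the HR waveform is not dictated by
the method description this follows; centring is the default and
convolution is intentionally not applied — the waveform is used
directly. The residual keeps its intercept contribution so percent
signal change (baseline window = all pre-injection volumes) stays
defined.

A two-stage procedure (nuisance residual, then task GLM) attenuates the
task beta by the R² of the task regressor on the nuisance columns,
because the task and the bradycardia both live after the onset. The
activation design therefore accepts extra confound columns and the
pipeline passes the HR regressor through; by the Frisch–Waugh theorem
the task estimate then equals the joint-model estimate and is unbiased.
This mirrors common practice of fitting all regressors in one model.

The HRF is the canonical double-gamma (peak 5 s, undershoot 15 s,
ratio 1/6). These are human-canonical values; the species-specific HRF
is unknown, so all parameters are exposed. The response block is a
single boxcar starting at the injection onset whose length is the
modelled response-epoch duration; the block-length sweep scores each
candidate by the mean t over the inferior-olive mask (peak-t and
voxel-count scores are options) and breaks ties toward the shortest
candidate (the most conservative model). All p-values are two-sided.

Group inference is a voxelwise one-sample t (df n−1) across session
betas with BH-FDR at q = 0.0005; per-session comparisons are paired t
against saline at uncorrected p = 0.005. Degenerate voxels (zero
residual or between-subject variance, relative tolerance 1e−12) are
flagged and reported with t = 0 / p = 1 rather than infinities.
Spatial smoothing (separable Gaussian, σ = FWHM/√(8 ln 2), zero-padded
boundaries, default FWHM 2.8 mm) is applied per frame inside the full
pipeline, mirroring conventional preprocessing; the bare session model
leaves it off so parameter-recovery comparisons are not diluted by ROI
boundary effects.

Cluster tables use 26-connectivity; coordinates are mm offsets from the
volume centre reported to one decimal, hemisphere from the sign of the
peak x (clusters spanning the midline are labelled L/R), and the area
is the atlas label at the peak voxel.

## Tremor index

Spectra are single-sided amplitude spectra of Hann-windowed, 10-s,
non-overlapping bins aligned to the baseline start (frequency
resolution 0.1 Hz at 100 Hz sampling; no window-gain compensation, so
a unit sinusoid appears at the Hann coherent gain 0.5 — the index is a
ratio, so the gain cancels). Band edges are half-open [lo, hi): 10 Hz
belongs to the tremor band, and the DC bin is excluded from the motion
band because the constant offset is gravity, not motion. "Amplitude"
versus "power" is a genuine ambiguity in how such indices are
described; amplitude is the default and power (squared spectrum) is an
option.

Ten-minute aggregation windows are aligned to the first bin; trailing
partial windows are dropped; the normaliser is the mean bin index over
the 30-min baseline. The duration endpoint has no canonical
definition, so an explicit stand-in rule is used: windows exceeding
baseline mean + 2·SD of the normalised baseline windows, longest
contiguous run (a total-time variant is an option, both configurable).
Trend statistics are pairwise paired t-tests on the maximum index and
a one-way ANOVA on durations; zero-variance comparisons are flagged,
not reported as infinite statistics.

## Connectivity

Epochs: pre-injection takes volume onsets in [0, 232] (closed), post
takes [234, 484) (half-open) — 117 and 125 volumes at TR 2 s. Rows are
demeaned within each epoch, so a split epoch never leaks the other
epoch's mean. Partial correlations come from the inverse sample
covariance; a singular covariance (possible at very short epochs)
falls back to a documented ridge (ε = 1e−8·trace/n) with a warning.
The residualisation route is retained as an independent implementation
and the two must agree to 1e−10.

The method description this package follows defines both a pre/post
difference and a drug-minus-saline subtraction; the saline-subtracted
post matrix, PC(drug post) − PC(saline post), is the primary output
and both per-condition post−pre differences are emitted alongside
rather than guessing a single composition. At the group level the
pipeline concatenates per-animal epoch-demeaned series before
computing the matrix.

The permutation test shuffles whole time samples of one ROI (simple
shuffling, no block structure — deliberately destroying auto- and
cross-correlation), recomputing the pair's partial correlation with
the conditioning set fixed; p = (1 + #{|null| ≥ |obs|})/(n_perm + 1),
two-sided, so p is never exactly zero. Default n = 2000, read at
p < 0.001.

## Beta–tremor regression

Observations are pooled across animals and sessions (drug fMRI session
k is paired with behavioural session k; a per-animal fit is exposed as
an option — with three sessions per animal the pooled fit is the only
well-powered choice, and no mixed-effects animal term is fitted at
n = 5). Per voxel: simple least squares of β on the maximum tremor
index; slope, t (df n−2) and two-sided p, thresholded at uncorrected
p = 0.05. Enrichment of suprathreshold voxels in a target ROI set is
summarised as an odds ratio with Haldane correction for empty cells.

## Problem sizes used in validation

The test-suite and the acceptance script validate on: 20 simulated
sessions for artifact-bias reduction and for 1%-amplitude recovery
(bias estimated by averaging the signed error over sessions); 20
saline sessions for false-positive calibration (background voxels,
which are mutually independent by construction, give a binomial
count); 10 seeds for the block-length sweep (majority vote over
candidates 5–60 s); 20 seeds for tolerance monotonicity; 200 samples
of a specified one-factor 6-ROI Gaussian (loadings 0.9…0.4, unit
noise) for partial-correlation recovery; 500 simulations at
n_perm = 200 for permutation calibration; 10 seeds for the
connectivity-change decline; and 20 three-animal experiments for the
beta–tremor enrichment. These sizes make the whole validation run in
a few minutes while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- White noise only: with temporally autocorrelated noise the GLM
  t-statistics would be optimistic; prewhitening is not implemented.
- The canonical HRF is a human default; a mis-specified HRF biases
  amplitude recovery (the block-length sweep absorbs some of this).
- The duration rule and the artifact-gain/heart-rate-drop magnitudes
  are explicit stand-ins for quantities with no published values.
- ROIs are cuboids; no spatial registration, geometry or
  partial-volume behaviour is modelled.
- The permutation test assumes exchangeability of time samples under
  the null; with strongly autocorrelated series it would be liberal.
  On the white-noise generator it is exactly calibrated.
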