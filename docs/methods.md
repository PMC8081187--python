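# Methods

This note documents the models implemented in `tactile_p300`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Paradigm model

A run is `blocks_per_run` (8) blocks of `trials_per_block` (13) trials of
`stimuli_per_trial` (6) stimuli. Targets last 150 ms (100 Hz drive),
disturbances 200 ms (23 Hz drive), with a 400 ms inter-stimulus interval.
Trial 0 of each block is six disturbances and marks the block start; each
later trial places exactly one target uniformly at random over the six
slots (a seeded draw; no constraint on consecutive placements). One site
(left or right index finger) is stimulated per block; the attended side
defaults to alternating left, right, … and equals the stimulated side
unless a caller decouples them (that path produces "ignored" target
labels). A target trial spans `150 + 5·200 + 5·400 = 3150 ms`: the
inter-stimulus interval counts only between stimuli — this convention
reproduces the protocol's stated 3.15 s trial exactly, so we adopt it. The
gap after a trial is a separate configurable (`inter_trial_gap`, default
0 ms). Onsets are integer milliseconds so events align exactly to samples
at 1,000 Hz. Stimulus drive waveforms (100 Hz sine / 23 Hz square) are not
synthesised; only event timing matters downstream.

## Synthetic EEG generator

`synth.simulate_run` renders a schedule into 30-channel (standard 10–20
subset) continuous EEG at 1,000 Hz containing:

- **P300**: a raised-cosine (Hann) bump, peak latency 350 ms, width 400 ms,
  amplitude 8 µV at the topography maximum, mixed through a Gaussian
  centro-parietal topography (maximal between Cz/CP1/CP2/Pz). It is added
  at attended-target onsets only. A raised cosine was chosen because any
  smooth unimodal positive deflection matches averaged-ERP morphology while
  having a closed-form peak and width for testing. 8 µV against 5 µV RMS
  noise gives a single-trial SNR low enough that single epochs look noisy
  but 96-trial grand averages are clean — typical of real P300 data.
- **Lateralised band power**: two independent band-limited (8–20 Hz) noise
  sources with Gaussian topographies centred on C3 and C4. In blocks
  attending the left hand the C4 (contralateral) source's drive is scaled
  by `sqrt(lateral_power_ratio)`, and symmetrically for the right. The
  default ratio 4 defines the fixed high-SNR study condition used by the
  acceptance checks. This is the discriminative signal CSP should find.
- **Background**: per-channel independent 1/f noise (PSD ∝ f^−1, RMS
  5 µV), generated by spectral shaping of white Gaussian noise.
- **Blinks** (default off): 300 ms Hann bumps, ~120 µV, mixed through a
  frontal (Fp1/Fp2-dominant) topography, Poisson-timed at `blink_rate` per
  minute. They exist to exercise the ICA-based EOG removal.

Simulations used by the tests and analysis drivers shorten the 60 s
inter-block break to 2 s: breaks carry no task-locked signal, and the
shorter gap keeps the continuous array small while leaving every
within-block timing untouched.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: volume-conducted correlated background (channels
are independent except for the planted sources), somatosensory steady-state
responses to the 23/100 Hz drives (mostly outside the 4–20 Hz
classification band), non-stationarity, electrode drift and movement
artifacts, and between-subject variability. Accuracies on this generator
are therefore upper bounds, not predictions for real cohorts.

## Preprocessing

Fixed order for the main analysis: re-reference to avg(TP9, TP10) →
0.5–30 Hz 4th-order Butterworth band-pass → optional ICA-based EOG removal
→ epoch −200..1000 ms around target onsets with −200..0 ms baseline
subtraction. Filtering is zero-phase (forward–backward, effective order 8,
no group delay) by default; a causal single-pass mode exists for real-time
emulation. Epoch windows include both endpoints at sample resolution (1201
samples at 1 kHz); sample 0 is the stimulus onset. Events whose window
leaves the recording are dropped and counted.

EOG removal substitutes an automatic two-threshold rule for expert
component inspection: a FastICA component is removed when ≥ 0.6 of its
squared mixing topography lies on Fp1/Fp2/F3/F4 **and** ≥ 0.5 of its source
power lies below 3 Hz (both configurable). FastICA's contrast cannot fully
converge on near-Gaussian subspaces (rotations there are unidentifiable —
and the synthetic background is exactly Gaussian), while the heavy-tailed
blink component is isolated early; hitting the iteration cap therefore
warns by default, and `on_nonconvergence="error"` raises with diagnostics.
An ECG channel, when present, is handled by a channel-drop list rather
than ICA.

## Spectral analysis

Welch PSD uses density scaling (integral over frequency ≈ variance).
ERSP/ITC use complex Morlet wavelets, σ_t = n_cycles/(2πf) with 7 cycles
and a linear 2–30 Hz grid by default; wavelets longer than the epoch are
allowed (convolution zero-pads; the resulting edge attenuation cancels in
the unit-normalised ITC and in the baseline-relative ERSP, and the tests
evaluate interior time points). ERSP is `10·log10(P/P_baseline)` with the
−200..0 ms baseline. ITC is `|mean_k c_k/|c_k||`; zero-magnitude
coefficients are skipped and counted, and a single-epoch ITC (identically
1) is flagged degenerate.

Band definitions: δ 0.5–3, θ 4–7, α 8–13, β 14–20 Hz. The β upper edge is
20 Hz to match the overall 0.5–20 Hz restriction of the analysis, and the
combined classification band is 4–20 Hz. Band selection keeps bands whose
CSP+classifier CV accuracy exceeds the exact 0.5 chance level of this
balanced two-class design.

## CSP

Per-trial covariances `E Eᵀ` are trace-normalized before averaging so
high-variance trials do not dominate, then shrunk toward `(tr Σ/N)·I`
(Ledoit–Wolf intensity estimated from the pooled samples by default —
needed for well-conditioned 30×30 estimates from ~1,000-sample epochs).
`scipy.linalg.eigh(Σ_A, Σ_A+Σ_B)` solves the generalized eigenproblem; its
B-orthonormalisation makes `W (Σ_A+Σ_B) Wᵀ = I` hold by construction.
Filters are ordered by eigenvalue (class-A variance share) descending;
`selected_idx` takes m from each end, default m = 3 (6 features — the
protocol's feature count; m = 6 is a supported alternative reading of
"largest and smallest six"). Signs are fixed by making each filter's
largest-magnitude pattern coefficient positive (ties → lowest channel
index). Features use the natural log — any base is a monotone affine
rescaling, irrelevant to LDA/SVM. The Eq. denominator sums the variances of
all 2m selected rows. CSP is fit on the 4–20 Hz filtered, 0–1000 ms
post-onset portion of left- vs right-attended target epochs.

## Classification and evaluation

LDA uses the pooled within-class covariance (`w = Σ_pooled⁻¹ (μ₁ − μ₀)`),
with Ledoit–Wolf shrinkage as a warned fallback if the pooled covariance is
singular. The optional SVM is RBF with C = 0.4 and γ = 1/(d·var(X))
(scikit-learn's "scale"). Cross-validation is stratified 10-fold
(stratification protects the 48+48 per-class counts); the band filter and
the CSP filters are fitted inside each training fold only. The sliding
window evaluator restricts epochs to 500 ms windows stepped by 100 ms
(0–1000 ms span → 6 windows) and re-runs the full CV per window.

## ITR

`B = log2 N + P log2 P + (1−P) log2((1−P)/(N−1))` with `0·log 0 := 0` at
the endpoints; `ITR = B·M` with M = 9.5238 decisions/min (one decision per
6.3 s, i.e. two 3.15 s trials). M is exposed as a free parameter rather
than derived from the trial length, since the decisions-per-trial mapping
is a protocol choice. Reported ITRs are rounded to 2 decimals only at the
presentation layer. One published operating point (98.50 % → 9.09 bits/min)
is inconsistent with the formula (which gives ≈ 8.45) and is deliberately
not reproduced.

## Problem sizes and numerical conventions

The canonical synthetic session is one full run (8 blocks, 96 target
epochs) — the protocol's own per-session size, which 10-fold CV and the
band table handle in seconds. Parameter-recovery checks use a high-SNR
variant (P300 20 µV, noise 2 µV RMS). Monte-Carlo checks use 1,000 draws
for the ITC expectation and ≥ 1,000 trials for schedule-uniformity
chi-square tests. BrainVision output supports MULTIPLEXED INT_16 (exact to
half a resolution step) and IEEE_FLOAT_32 (bit-exact for float32 data);
other dialects are rejected explicitly. Marker positions are 1-based on
disk, 0-based in memory; event intervals are half-open.

## Known limitations

- The generator's independence assumptions (see above) make classification
  easier than on real EEG; published real-cohort accuracies are not
  reproducible desk-side and are not claimed.
- The ICA-based EOG rule is a deterministic stand-in for expert judgement;
  thresholds were set against the planted blink model, not human data.
- ERSP/ITC edge samples (within a wavelet half-support of the epoch edge)
  are attenuation-biased; analyses should read interior time points.
- Grand-average peak search uses the positivity convention within
  250–450 ms; negative or out-of-window components need explicit windows.
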