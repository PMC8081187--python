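# tactile-p300

Analysis pipeline for a two-site **tactile P300 brain–computer interface**:
an oddball protocol delivers rare 100 Hz target pulses among frequent 23 Hz
disturbance pulses to the left or right index finger, and the attended side
is decoded from 30-channel EEG. The package is aimed at BCI researchers who
want a tested, fully synthetic-verifiable implementation of the classical
processing chain: oddball stimulus scheduling, preprocessing, frequency-band
selection, CSP spatial filtering, LDA/SVM classification with stratified
cross-validation, sliding-window evaluation, and information-transfer-rate
reporting. Because no public recording accompanies this paradigm, the
package ships a synthetic EEG generator with planted ground truth (P300
deflection, lateralised band power, 1/f noise, blinks) so every stage can be
validated end to end.

## The method

**Protocol.** A run is 8 blocks × 13 trials × 6 stimuli. The first trial of
each block is all disturbances (block marker); each later trial hides one
target (150 ms) among disturbances (200 ms) with 400 ms inter-stimulus
intervals, so a target trial spans 150 + 5·200 + 5·400 = 3150 ms. Only one
site is stimulated per block and the subject attends it.

**CSP.** For single-trial data `E` (N channels × T samples) the spatial
filter is `Z = W E`, where the rows of `W` solve the generalized
eigenproblem `Σ_A w = λ (Σ_A + Σ_B) w` built from the trace-normalized,
shrinkage-regularised average covariances of the left- and right-attended
classes — simultaneous diagonalization of the two class covariances. The
`m` filters from each end of the eigenvalue spectrum (default m = 3) give
log-variance features

```
x_p = log( var(Z_p) / Σ_i var(Z_i) ),   i = 1..2m,
```

which feed an LDA (or RBF-SVM, C = 0.4) classifier under stratified 10-fold
cross-validation. Band selection scores each rhythm band (δ 0.5–3, θ 4–7,
α 8–13, β 14–20 Hz; 4th-order Butterworth, zero-phase) with the same
pipeline and keeps bands above chance; the combined classification band is
4–20 Hz.

**ITR.** Decisions at accuracy `P` over `N = 2` commands carry
`B = log2 N + P log2 P + (1−P) log2((1−P)/(N−1))` bits; at
`M = 9.5238` decisions/min the information transfer rate is `ITR = B·M`
bits/min.

## Worked example

The numbered drivers under `analysis/` run the whole study on the canonical
synthetic session (fixed seeds, 96 attended-target epochs) and write tables
under `results/`:

```
$ python analysis/01_simulate.py
schedule: 624 stimuli in 8 blocks (96 targets, 96 attended)
trial duration: 3150 ms
recording: 30 channels x 344000 samples at 1000 Hz (344 s)

$ python analysis/02_erp.py
attended targets (n=96): Cz peak 6.28 uV at 336 ms (planted: 8.0 uV at 350 ms)
disturbances (n=95): Cz peak 0.22 uV — no planted deflection, noise floor only

$ python analysis/03_bands_csp_classify.py
per-band CV accuracy:
  delta   0.5- 3.0 Hz  0.576 +/- 0.141
  theta   4.0- 7.0 Hz  0.492 +/- 0.189
  alpha   8.0-13.0 Hz  0.852 +/- 0.106
  beta   14.0-20.0 Hz  0.959 +/- 0.053
combined 4-20 Hz CSP(m=3)+LDA: 0.989 +/- 0.035

$ python analysis/04_itr.py
reference_best             P=1.0000  B=1.0000 bits  ITR=9.52 bits/min
synthetic_session          P=0.9889  B=0.9119 bits  ITR=8.69 bits/min
```

Reading the output: the grand average recovers the planted P300 (peak near
350 ms at Cz; the attenuation from 8 to ~6 µV is the 0.5–30 Hz filter and
baseline noise), disturbance epochs stay at the noise floor, the
discriminative information concentrates in the α/β bands that carry the
planted lateralised power (δ/θ hover near the 0.5 chance level), and the
combined 4–20 Hz model converts a 98.9 % CV accuracy into 8.69 bits/min.

A single declarative config can run the same chain in one call:

```python
from tactile_p300.pipeline import config_from_dict, run_pipeline
report = run_pipeline(config_from_dict({"seed": 9}), outdir="results/run")
```

## Layout

- `src/tactile_p300/` — library: `paradigm` (scheduling), `synth`
  (generator), `io_formats` (BrainVision + events TSV), `preprocess`
  (filter/re-reference/epoch/ICA-EOG), `spectral` (PSD/ERSP/ITC/band bank),
  `csp`, `classify`, `metrics`, `pipeline`.
- `analysis/` — numbered narrative drivers writing `results/` tables.
- `tests/` — unit, property, and acceptance tests.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
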