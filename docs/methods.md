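# Methods

## The problem

A P300-based brain-computer interface lets an operator issue one of four
movement commands (forward, right-turn, left-turn, backward) by attending to
one of four flashing stimuli. The attended stimulus elicits a P300
event-related potential — a positive EEG deflection peaking roughly 300 ms
after the flash — while unattended stimuli do not. The classification
problem is hard for two reasons: the P300's latency varies by tens of
milliseconds from trial to trial, and its amplitude (10–25 µV) is of the
same order as the background EEG.

This package implements the full decision pipeline — time-shift template
correlation, a small feedforward network, and two sequential decision
modes — together with a synthetic session generator so every stage is
testable without recordings or hardware.

## Paradigm timing

One trial lasts 1050 ms: four stimuli flash right-to-left for 100 ms each
with a 100 ms inter-stimulus interval, followed by a 250 ms inter-trial
pause. The P300 window of stimulus *k* nominally opens 81 ms after its
flash (i.e. at 200·k + 81 ms from trial onset) and spans 280 ms = 70 samples
at 250 Hz. At 250 Hz the nominal start is off the 4 ms sample grid; window
starts are snapped **up** to 84/284/484/684 ms (a `grid_snap="nearest"`
option rounds instead). Sample windows are half-open `[start, end)`,
0-based, and times are stored in milliseconds as floats.

Two timing facts follow from the paradigm itself and surface in tests:

* consecutive P300 windows overlap by 80 ms, so the window *after* the
  attended interval always sees part of the target P300 — non-target
  epochs adjacent to the target are not signal-free even without noise;
* the 1050 ms trial pitch is not a multiple of the 4 ms sample period, so
  every second trial onset falls between samples. Exactness tests
  (shift recovery) therefore use single trials starting at time zero.

## Preprocessing

The analysis signal is the pointwise mean of the Cz, Pz and Oz channels.
Each epoch is min-max normalized to [0, 1] (a constant window maps to all
0.5 by convention) and carries a raw 100-sample context (±60 ms) used by
the shift search. A zero-phase 8–30 Hz band-pass plus 60 Hz notch filter
(`bandpass_notch`) is provided for raw external recordings; forward-backward
filtering is used so no group delay is added to the latency being measured.
Synthetic sessions are generated already band-limited (emulating an
amplifier that filters before digitization) and are not re-filtered by
default — a digital 8–30 Hz re-filter would remove most of the energy of
the slow P300 deflection itself, which real hardware digitizes after
analog filtering.

## Time-shift correlation features

The subject's template Q is the mean of (by default ten) normalized
target-interval epochs from a labeled training session, re-normalized to
[0, 1]. For an acquired epoch the 70-sample acquisition window slides from
−60 ms to +60 ms in 4 ms steps (one sample) over the raw context; each
slice is independently min-max normalized and correlated with Q by the
Pearson product-moment correlation. This yields 31 features r₁…r₃₁, with
r₁₆ the unshifted correlation. A matched epoch gives a bell-shaped curve
whose argmax encodes the latency offset exactly (a δ ms injected latency
moves the argmax by δ/4 positions); a mismatched epoch gives an irregular
low curve. Constant slices correlate at 0 by convention (the formula is
0/0 there). Shifts reuse real context rather than zero-padding, avoiding
edge artifacts; per-slice normalization is kept for fidelity to the
normalize-then-correlate order even though the correlation itself is
affine-invariant.

## Network and training

The classifier is a 31-15-1 feedforward network: tanh-sigmoid hidden units
f(N) = 2/(1+e^(−2N)) − 1 and a **linear** output unit, giving
m(n+2)+1 = 496 parameters. The linear output is deliberate: trained scores
fall freely around the 0/1 targets (e.g. 0.0233 or 0.9473), and the
decision threshold of 0.6 (strict `>`) separates them.

Training is batch gradient descent on the mean squared error over a
70/15/15 split (training / generalization test / early stop; seeded
shuffle), learning rate 0.01, up to 9000 epochs or an MSE goal of 1e−5,
with optional momentum (off by default). Early stopping restores the
weights with the best stop-partition error. The patience is 2000 epochs,
not a small window: plain batch gradient descent produces a transient hump
in the stop-partition error during its early plateau (a minimum near epoch
50, a mild rise to ~epoch 300, then descent to convergence), and a short
patience aborts inside the hump with roughly triple the converged training
error. Weight initialization is uniform, scaled by layer fan-in, seeded;
all randomness (split, init) derives from the one `TrainingConfig.seed`.

The threshold is stored with the model but is a choice, not a fit: a
diagnostic report (`threshold_diagnostic`) scores a random subset of
labeled trials and summarizes the target / non-target output ranges the
way the operating threshold was originally selected by inspection.

## Decision modes

A trial is **legal** when exactly one of the four interval scores exceeds
the threshold; zero (`illegal_none`) or several (`illegal_multiple`)
super-threshold scores make it illegal.

* **FM (fast recognition)** decides from the latest legal trial. On an
  illegal trial the raw epochs are stored and averaged with the next
  trial's (per interval, raw contexts averaged, then renormalized,
  featurized and re-scored). At most 5 trials accumulate; a 5th
  consecutive illegal trial erases the buffer and emits a non-recognition.
* **AM (accuracy recognition)** consumes only legal trials: a command is
  issued when the same label occurs twice among the last three legal
  trials; three distinct labels drop the oldest and the vote continues.
  AM uses single-epoch legal trials (no FM-style accumulation inside the
  voting loop).
* **Averaging baselines** classify non-overlapping blocks of 1, 2 or 3
  trials with no carry-over; an illegal block is a non-recognition.

Stimulus labels are 0-based internally and reported as 1-based ordinals
("the second stimulus").

## Session metrics

Every trial is attributed to the decision event that consumed it: trials
accumulated into a command inherit its correctness (judged against the
truth at the emission trial), trials consumed by an erase or an illegal
block — and trials left pending at session end — count as non-recognition.
Correct + wrong + non-recognition therefore always equals the trial count,
and the per-trial correct rate is the accuracy measure used for mode
comparisons. Experimental time T_exp is full elapsed session time
(n_trials × 1.05 s), including non-recognized trials.

ITR follows the Wolpaw convention: bits per selection
log₂K + P·log₂P + (1−P)·log₂((1−P)/(K−1)) with K = 4 choices and P the
*command* accuracy (correct commands over emitted commands), times
60/CTI where CTI = T_exp / (number of correct commands).

The wrong-recognition accumulation rate is Er_i = En_i / Et (cumulative
wrongs over total wrongs), a non-decreasing curve that ends at 1; a late
steep rise indicates fatigue-clustered errors. A variant form
(En−Et)/Et — the same curve shifted to [−1, 0] — is available behind
`printed_form=True`; the default is the form on which statements like
"the rate exceeds 0.5 after 50 trials" are meaningful. A session without
wrong recognitions has no defined rate and is flagged.

Trajectory comparison resamples both paths to a common arc-length
parameterization (200 points), correlates their lateral-deviation profiles
relative to the desired path's start-to-end chord, and reports the
total-length difference in percent. Which coordinate to correlate is a
convention; lateral deviation after arc-length resampling makes the
measure invariant to sampling density and captures "did it follow the
taped line". Two straight paths along the chord (both profiles constant)
correlate at 1 if identical.

## The synthetic session generator

The generator emulates the acquisition conditions, not the biophysics:

* **P300**: a Gaussian bump (σ = 40 ms) peaking 300 ms after the attended
  stimulus's flash, amplitude 15 µV (the reported 10–25 µV range) with
  ±20% uniform per-trial variability, added identically to all three
  channels. Only the attended interval receives a bump.
* **Latency jitter**: uniform on ±20 ms by default (least-informative
  within the stated 250–500 ms latency band), bounded by the ±60 ms shift
  search; drawn per trial and recorded as ground truth.
* **Background noise**: white Gaussian filtered to 1–30 Hz, independent
  per channel, rescaled to a 10 µV standard deviation. The band extends
  below the 8–30 Hz analysis band on purpose: background with no energy
  at P300 frequencies is nearly orthogonal to the template, which makes
  false-positive (legal-but-wrong) trials vanishingly rare and the
  discrimination task unrealistically easy. Including the 1–8 Hz range
  puts P300-scale slow fluctuations into non-target windows, which is
  both closer to real EEG spectra and necessary for the decision modes to
  face genuine wrong recognitions.
* **Fatigue** (off by default): a linear per-trial drift — amplitude
  factor (1 − r·i) and jitter half-width (1 + r·i), clipped at 60 ms — as
  a synthetic-only stand-in for the reported phenomenon; no model of it
  is fitted to data.
* **Determinism**: one `numpy` generator seeded from `config.seed`; per
  trial the jitter is drawn before the amplitude factor, so identical
  configs are bit-identical.

The default noise level was calibrated once so that the trained pipeline's
single-epoch accuracy on held-out sessions sits near 0.9 (the regime where
comparing decision modes is informative — measured ≈ 0.84 across seeds),
and then frozen.

Truth sequences for mode comparisons come from `blocked_targets`: the
attended stimulus is constant for blocks of 5 trials, emulating an
operator holding a command until it is recognized — the assumption under
which FM's cross-trial averaging and AM's voting are meaningful.

What the generator does **not** model: 1/f spectra, ocular or muscle
artifacts, electrode drift, cross-channel correlation structure,
per-subject morphology differences, or any blink-based triggering.
Passing tests demonstrate that the algorithms are implemented correctly
and behave as designed under controlled conditions; they do not predict
accuracy on human EEG.

## Problem sizes and numerical choices

* Evaluation experiments use a 160-trial training session and 100-trial
  test sessions (30 of them for the mode-ordering sign test), the session
  sizes of the reference protocol.
* `ppmcc` clips rounding excursions to [−1, 1]; correlations of constant
  vectors are 0; min-max normalization of a constant window is 0.5.
* EDF files are written 16-bit with per-channel scaling over the full
  digital range (quantization error < span/65535); delimited-text
  recordings round-trip bit-exactly (`%.17g` + round-trip parsing).
* Model files are JSON at full precision so tests can pin exact values.

## Known limitations

* The trainer is plain batch gradient descent; it is deterministic and
  sufficient for this feature space but slower to converge than
  second-order or adaptive methods, and its early-stopping patience must
  stay large (see above).
* AM's behaviour when the vote window repeatedly fills with three
  distinct labels is "drop the oldest and continue", applied indefinitely.
* T_exp accounting includes all elapsed trials; a deployment that pauses
  stimulation during non-recognition would score a higher ITR.
* The EDF writer emits a minimal single-record file (one data record
  spanning the recording) — valid EDF, but not suitable for streaming
  appends.
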