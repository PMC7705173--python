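# Methods

## Decoding problem and pipeline

The package decodes the walking phase at 100 Hz from two parallel
biosignal streams. Ground truth comes from binary foot-switch contact
traces: a sample is RIGHT when only the right foot is off the ground, LEFT
when only the left foot is off, STANCE when both feet are down. The EEG
decoder solves the coarser 2-class task SWING (a step with either leg) vs.
STANCE, reflecting the difficulty of lateralizing lower-limb activity in
scalp recordings; the EMG decoder solves the full 3-class task.

A session is split 60/15/25 into contiguous, time-ordered training,
validation and test segments. Both networks are first fit on the training
split; their confusion matrices on the validation split calibrate the
fusion; the networks are then refit on training+validation, and everything
is scored on the test split only, emulating an online deployment where the
usage-time data always follows calibration. Splitting is contiguous on
purpose: overlapping windows would leak gait-cycle context between
shuffled splits.

### Windowed features

Both signals are segmented into rectangular 50 ms windows with 80% overlap
(10 ms hop → 100 decisions/s). Inside each window:

* EEG: common average reference across channels, zero-phase 4th-order
  Butterworth band-pass to 1–8 Hz, per-channel z-score within the window,
  then the mean of the trailing non-overlapping 20% (the block average) —
  one scalar per channel per window.
* EMG: zero-phase 8th-order Butterworth band-pass 10–250 Hz, full-wave
  rectification, zero-phase 4th-order 6 Hz low-pass envelope, block
  average. This pipeline is positively homogeneous — scaling the signal by
  a scales every feature by exactly a — which is precisely the mechanism by
  which amplitude attenuation reaches the decoder.

Zero-phase filtering is forward–backward application of the stated design
order with odd-symmetric reflection padding of length
min(3·(order+1), window−1). On 50-sample windows the padding choice is
consequential, so it is fixed and documented rather than left to library
defaults. Non-integer window/step sample counts at arbitrary rates are
rounded; timestamps derive from sample indices. A window/channel whose
filtered standard deviation is below 1e−9 of the raw window RMS is treated
as degenerate and z-scores to zeros — this guards against amplifying the
O(1e−16) rounding residue that the common average reference leaves on
channels it annihilates.

The per-window label is the majority vote over the same trailing block the
feature summarizes; exact ties resolve to STANCE, so ambiguity never
commands a step. For the EEG task, RIGHT and LEFT count as SWING before
voting.

### Decoders

Both decoders are stacked-LSTM sequence classifiers with a
time-distributed softmax head, implemented in numpy (forward pass,
truncated backpropagation through time, Adam, global-norm gradient
clipping at 5). Defaults: EEG two layers of 250 and 150 units, EMG one
layer of 150 units; cross-entropy loss; learning rate 1e−3; batch 32;
training sequences are contiguous non-overlapping runs of 100 windows
(1 s); early stopping with patience 10 on a held-out trailing 10% of the
training sequences; optional inverse-frequency class weighting (off by
default). Every stochastic step is driven by one seed, so training is
bit-reproducible. Features are standardized with training-split statistics
stored in the decoder, so a test-time amplitude change is seen exactly as
the shifted, compressed input distribution it is. Inference is stateful by
default (recurrent state carried across the whole test stream, emulating
online use); a stateless mode resetting every sequence is provided, and
both agree on the first window by construction.

### Fusion

Each classifier's validation confusion matrix (rows true, columns
predicted) is column-normalized into conditionals P(true=c_i | pred=c_j),
with add-α smoothing (α = 1 by default; α = 0 reproduces the raw
normalization and is undefined for a class the classifier never
predicted). The belief of each fused class is the product of the two
conditionals and the class prior, with the EEG SWING conditional reused
for both RIGHT and LEFT. Priors are uniform (cadence unknown); a
`literal_prior_weighting` flag exposes the uncollapsed multi-classifier
weighting Π_k P(c_i|e_k) / P(c_i)^(K−1), which differs from the default
only for non-uniform priors. Fusion consumes hard predictions, not
posteriors; posterior-weighted (soft) fusion is deliberately out of scope.
Exact belief ties resolve by the fixed preference STANCE > RIGHT > LEFT.

## Impairment regimes

* **Temporary (fatigue-like).** The EMG of the validation and test splits
  is multiplied by a retained-amplitude fraction (1.0, 0.9, 0.5, 0.3, 0.1
  by default); the training split is never touched, and the pipeline
  asserts this with a hash check. "Attenuation of X%" always means
  retained fraction 1 − X/100. Validation and test fractions can be set
  independently to study calibration at a mismatched (±10% amplitude)
  degradation level. Fusion conditionals are recomputed per level on the
  attenuated validation split.
* **Permanent (paresis-like).** Only the vastus medialis channel of each
  leg is retained, the whole recording is attenuated to 30% amplitude, and
  per-channel Gaussian noise is added at a target SNR (10, 3, 1.5, 1, 0.5,
  0.1 dB), on all three splits alike — the impairment is steady, so the
  decoders train on degraded data too. Signal power for the SNR is the
  channel's mean squared amplitude over the whole attenuated recording (no
  attempt is made to separate "informative" EMG from background, which
  would require a separation procedure that cannot be specified
  reproducibly); noise σ = sqrt(P_signal / 10^(SNR/10)), added to the raw
  signal upstream of all processing, with split-specific sub-seeds.

## Synthetic sessions

No public gait EEG+EMG corpus with foot-switch ground truth is available,
so experiments run on a seeded generator that reproduces the statistical
structure the decoders rely on. One (parameters, seed) pair defines one
synthetic subject.

* **Gait clock.** A square-wave model: one cycle clock (default stride
  1.2 s, per-cycle Gaussian jitter σ = 0.05 s, boundaries snapped to
  integer samples so the jitter-free sequence is exactly periodic), legs
  half a cycle apart, per-leg stance fraction 0.62. Any stance fraction
  above 0.5 guarantees two double-support intervals per cycle; parameter
  sets whose swing intervals would overlap (simultaneous flight) are
  rejected as non-walking. Foot-switches are one heel and one toe trace
  per foot (heel covers the first ¾ of stance, toe from 20% of stance to
  toe-off; stance is their union). Samples with both feet off — possible
  under jitter — inherit the previous valid label.
* **EMG.** Six muscles (TA/VM/BF per leg) with textbook activation timing
  (TA in swing and at heel strike, VM in early stance, BF in late swing):
  Gaussian activation envelopes on the leg's cycle phase (burst gain
  80 µV) multiply a band-limited unit-RMS noise carrier (25–150 Hz), plus
  8 µV baseline noise. Burst timing is phase-locked, so the classes are
  separable; amplitudes are not biomechanically calibrated.
* **EEG.** 16 channels. Each carries a stride-locked constant-envelope
  frequency-modulated component — an even stride harmonic near the center
  of the 1–8 Hz band whose instantaneous frequency sweeps within the band
  twice per stride. Even harmonics make the waveform identical for right
  and left swing, so the EEG stream carries swing-vs-stance information
  only; the constant envelope keeps band power uniform over the cycle, so
  the class information is carried by the amplitude contrast alone. The
  component's amplitude is gain·(1 + contrast·swing(t)) with a smoothed
  swing indicator; defaults: peak gain 4 µV over the central channels
  (Gaussian spatial profile, floor 10%), contrast 6, on top of 12 µV of
  1/f background noise. These values were chosen so that, after the
  per-window z-scoring of the feature pipeline (which discards absolute
  amplitude and leaves only the within-window waveform coherence), the
  2-class EEG decoder lands clearly above chance yet well below the EMG
  decoder's clean performance — the operating regime in which fusion is
  interesting.

What the generator does **not** emulate: gait kinematics and kinetics,
ocular/muscular/cable EEG artifacts (the offline artifact-removal stage of
real pipelines is out of scope here; the synthetic EEG is clean enough for
the online path alone), electrode impedance drift, treadmill speed beyond
the cycle duration, inter-subject variability beyond the seed, and
physiological fatigue dynamics (median-frequency shifts). Consequently,
passing results establish the correctness and the qualitative behavior of
the decoding/fusion machinery under amplitude and SNR degradation — not
clinical performance on human recordings.

## Scaled-down experiment sizes

The shipped integration tests and `scripts/acceptance.py` use a 10-minute
session at 1 kHz, decoders of 64+48 (EEG) and 48 (EMG) units, and at most
10 training epochs. At 16 EEG channels and 6 EMG envelope features the
class structure is low-dimensional, and decoder capacity is not the
binding factor; the reduced sizes reproduce the same qualitative
degradation behavior as the full-size defaults while keeping a desk-scale
budget. The full-size networks remain the package defaults.

## Known limitations

* The LSTM implementation is minimal by design (no CUDA, no cuDNN-style
  fusion, float32 parameters); it is adequate for the feature
  dimensionalities here, not for raw-signal decoding.
* Metrics are computed per decision window; no event-level (step
  onset/offset) scoring is provided.
* Statistical tests across subjects (rank tests, post-hoc corrections) are
  not reimplemented; `compare_conditions` exports a long-format table for
  external statistics instead.
* The EEG-only decoder is scored on its own 2-class task; a 3-class
  EEG-only decoder is intentionally absent (the EEG stream is modeled as
  leg-agnostic).
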