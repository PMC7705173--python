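# gaitfuse

Hybrid EEG+EMG decoding of gait phases with confusion-matrix-calibrated
Bayesian belief fusion.

## The problem

Surface EMG decodes walking phases (right swing / left swing / double
stance) very accurately — as long as the muscles behave. Fatigue attenuates
the EMG amplitude at usage time; paresis permanently leaves few usable
muscles with low amplitude and poor signal-to-noise ratio. EEG-based
decoding of gait is far less accurate, but it does not depend on muscular
integrity. A hybrid human–machine interface (hHMI) fuses both streams so
that the decision is driven by whichever classifier is reliable for each
class: the EMG network tells the legs apart, the EEG network arbitrates
swing versus stance when the EMG degrades.

`gaitfuse` implements the full decoding stack for researchers in
neurorehabilitation and BCI who want to study classifier fusion under
controlled signal degradation:

* a seeded synthetic generator of treadmill-walking sessions (foot-switch
  contacts, gait-phase-locked EMG bursts, gait-locked low-frequency EEG
  modulations over central channels) standing in for human recordings;
* the windowed feature pipelines (50 ms rectangular windows, 80% overlap →
  100 Hz decision rate; per-window CAR + 1–8 Hz zero-phase Butterworth +
  z-scoring for EEG; 10–250 Hz band-pass, rectification and 6 Hz envelope
  for EMG; block average of the trailing non-overlapping 20%);
* two LSTM decoders (EEG → {SWING, STANCE}, two layers of 250/150 units;
  EMG → {RIGHT, LEFT, STANCE}, one layer of 150 units) implemented in
  numpy with truncated BPTT and Adam;
* the Bayesian belief fusion of their hard predictions;
* two simulated EMG impairment regimes and the evaluation machinery.

## The fusion rule

Each classifier *k* is characterized on a held-out validation split by its
confusion matrix `n_ij^k` (rows: true class, columns: predicted class),
column-normalized into conditional reliabilities

    P(c_i | e_k = c_j) = n_ij^k / Σ_i n_ij^k .

Given the per-window hard predictions `e_EEG` and `e_EMG`, the belief of
each fused class c_i ∈ {RIGHT, LEFT, STANCE} is

    Bel(c_i) = P_EEG(map(c_i) | e_EEG) · P_EMG(c_i | e_EMG) · P(c_i),

where `map` sends both RIGHT and LEFT to the EEG class SWING (the EEG
network contributes identically to either leg's swing) and STANCE to
STANCE. The fused decision maximizes the belief; priors are uniform; exact
ties resolve deterministically as STANCE > RIGHT > LEFT so ambiguity never
commands a step.

## Worked example

```python
import gaitfuse as gf
from gaitfuse.decoders import NetworkSpec

config = gf.RunConfig(
    gait=gf.GaitCycleParams(duration=240.0),          # 4 min of walking at ~0.83 Hz stride
    eeg_net=NetworkSpec(lstm_units=(48, 32), n_classes=2, max_epochs=10),
    emg_net=NetworkSpec(lstm_units=(48,), n_classes=3, max_epochs=10),
    temporary_levels=(1.0, 0.5, 0.3, 0.1),            # retained EMG amplitude fractions
    permanent_snrs_db=(10.0, 0.1),                    # VM-only + 70% attenuation + noise
    seed=11,
)
bundle = gf.run_experiment(config)

eeg = bundle.reports[("eeg", "none", "clean")]
print(f"EEG decoder (swing/stance) test accuracy: {eeg.accuracy:.3f}")
for regime, level in [("temporary", 1.0), ("temporary", 0.3), ("permanent", "0.1dB")]:
    emg = bundle.reports[("emg", regime, level)]
    fused = bundle.reports[("fused", regime, level)]
    print(regime, level, f"EMG {emg.accuracy:.3f} fused {fused.accuracy:.3f} "
          f"stance recall {emg.recall['STANCE']:.3f} -> {fused.recall['STANCE']:.3f}")
```

prints (about a minute on one CPU):

```
EEG decoder (swing/stance) test accuracy: 0.948
temporary 1.0 EMG 0.865 fused 0.933 stance recall 0.591 -> 0.911
temporary 0.3 EMG 0.488 fused 0.680 stance recall 0.033 -> 0.844
permanent 0.1dB EMG 0.783 fused 0.941 stance recall 0.163 -> 0.841
```

Reading it: with intact EMG the fused decoder matches the EMG decoder; when
the EMG amplitude drops to 30% the EMG-only accuracy collapses (it stops
seeing double stance almost entirely, stance recall 0.03) while the hybrid
stays far above it because the EEG stream keeps flagging stance. In the
permanent regime (only the vastus medialis of each leg, 30% amplitude,
0.1 dB SNR) the hybrid holds ~0.94 accuracy and ~0.84 stance recall.

The same pipeline is scriptable from the shell (`gaitfuse simulate`,
`preprocess`, `train`, `degrade`, `fuse-calibrate`, `decode`, `evaluate`,
`run-experiment`); see `gaitfuse --help`.

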