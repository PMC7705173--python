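"""End-to-end experiment orchestration.

One run: simulate a session -> split 60/15/25 in time order -> extract EEG
and EMG window features -> train both decoders on the training split ->
calibrate the Bayesian fusion on the validation split -> retrain the decoders
on training + validation -> apply an EMG impairment regime -> decode the test
split -> score EMG-only, EEG-only, and fused decision streams.

Protocol contracts enforced here (and asserted at run time):

* splits are contiguous and time-ordered (train -> validation -> test), so
  usage-time data always follows calibration data and overlapping windows
  never leak gait-cycle context across splits;
* fusion conditionals are estimated on the validation split only;
* in the temporary regime the decoders only ever see unaltered training
  signals (the training split hash is checked before/after degradation).

One synthetic "subject" is one seed; multi-subject experiments are seed lists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoders import NetworkSpec, predict, retrain_on_train_plus_validation, train_decoder
from .degradation import PermanentAlteration, TemporaryAlteration, apply_experiment
from .evaluation import MetricsReport, compare_conditions, score
from .fusion import FusionModel, fuse_sequence
from .preprocessing import WindowSpec, eeg_window_features, emg_window_features
from .signal import EEG_CLASSES, GAIT_CLASSES, MultichannelSignal
from .synthetic import (
    CorticalModel, GaitCycleParams, MuscleModel, SyntheticSession,
    default_muscles, simulate_session,
)

__all__ = ["RunConfig", "ExperimentBundle", "split_session", "run_experiment"]

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible experiment run depends on."""

    gait: GaitCycleParams = GaitCycleParams()
    cortical: CorticalModel = CorticalModel()
    muscles: tuple[MuscleModel, ...] | None = None
    window: WindowSpec = WindowSpec()
    eeg_net: NetworkSpec = field(default_factory=NetworkSpec.eeg_default)
    emg_net: NetworkSpec = field(default_factory=NetworkSpec.emg_default)
    fusion_alpha: float = 1.0
    split_fractions: tuple[float, float, float] = (0.60, 0.15, 0.25)
    temporary_levels: tuple[float, ...] = (1.0, 0.9, 0.5, 0.3, 0.1)
    permanent_snrs_db: tuple[float | None, ...] = (None, 10.0, 3.0, 1.5, 1.0, 0.5, 0.1)
    run_temporary: bool = True
    run_permanent: bool = True
    stateful_prediction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 or f >= 1 + 1e-12 for f in self.split_fractions):
            raise ValueError("split fractions must lie in [0, 1]")


@dataclass
class ExperimentBundle:
    """All reports of one run, keyed by (decoder, regime, level)."""

    reports: dict[tuple[str, str, object], MetricsReport]
    fusion_models: dict[tuple[str, object], FusionModel]
    guards: dict
    config_seed: int

    def comparison(self) -> pd.DataFrame:
        return compare_conditions(self.reports)

    def to_json(self) -> dict:
        return {
            "seed": self.config_seed,
            "guards": self.guards,
            "reports": {
                f"{dec}|{reg}|{lvl}": rep.to_dict()
                for (dec, reg, lvl), rep in self.reports.items()
            },
        }

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_json(), indent=2))
        self.comparison().to_csv(outdir / "comparison.csv", index=False)
        for (regime, level), model in self.fusion_models.items():
            model.to_json(outdir / f"fusion_{regime}_{level}.json")


def split_session(session: SyntheticSession, fractions=(0.60, 0.15, 0.25),
                  min_samples: int = 1) -> dict[str, SyntheticSession]:
    """Contiguous time-ordered train/validation/test slices of a session.

    Concatenating the three slices reproduces the session sample-for-sample.
    A split with a nonzero fraction but fewer than ``min_samples`` samples
    (e.g. shorter than one analysis window) is an error; zero fractions give
    empty splits.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValueError("need three fractions summing to 1")
    n = session.labels.n_samples
    b1 = int(np.floor(n * fractions[0]))
    b2 = int(np.floor(n * (fractions[0] + fractions[1])))
    bounds = {"train": (0, b1), "validation": (b1, b2), "test": (b2, n)}
    out = {}
    for name, (start, stop) in bounds.items():
        frac = fractions[SPLITS.index(name)]
        if frac > 0 and stop - start < min_samples:
            raise ValueError(f"{name} split shorter than {min_samples} samples")
        out[name] = session.slice(start, stop)
    return out


def _hash_signal(sig: MultichannelSignal) -> str:
    return hashlib.sha256(np.ascontiguousarray(sig.samples).tobytes()).hexdigest()


def _child_seed(ss_iter) -> int:
    return int(next(ss_iter).generate_state(1)[0] % (2**31))


def run_experiment(config: RunConfig) -> ExperimentBundle:
    """Run the configured impairment experiments on one synthetic subject."""
    ss = iter(np.random.SeedSequence(config.seed).spawn(64))
    session = simulate_session(
        params=config.gait,
        muscles=list(config.muscles) if config.muscles is not None else default_muscles(),
        cortical=config.cortical,
        seed=_child_seed(ss),
    )
    w_samples, _, _ = config.window.sample_counts(session.sampling_rate)
    splits = split_session(session, config.split_fractions, min_samples=w_samples)

    # ----- EEG path: identical across every EMG degradation condition -----
    eeg_feats = {
        name: eeg_window_features(s.eeg, config.window, labels=s.labels)
        for name, s in splits.items()
    }
    eeg_spec = dataclasses.replace(config.eeg_net, seed=_child_seed(ss))
    eeg_initial = train_decoder(eeg_feats["train"], eeg_spec)
    eeg_final = retrain_on_train_plus_validation(
        dataclasses.replace(config.eeg_net, seed=_child_seed(ss)),
        eeg_feats["train"], eeg_feats["validation"],
    )
    eeg_val_pred, _ = predict(eeg_initial, eeg_feats["validation"],
                              stateful=config.stateful_prediction)
    eeg_test_pred, _ = predict(eeg_final, eeg_feats["test"],
                               stateful=config.stateful_prediction)
    eeg_report = score(eeg_feats["test"].labels, eeg_test_pred, EEG_CLASSES)

    reports: dict[tuple[str, str, object], MetricsReport] = {}
    fusion_models: dict[tuple[str, object], FusionModel] = {}
    guards: dict = {
        "split_fractions": list(config.split_fractions),
        "split_samples": {k: int(v.labels.n_samples) for k, v in splits.items()},
        "calibration_split": "validation",
        "calibration_n_windows": int(eeg_feats["validation"].n_windows),
        "eeg_test_accuracy": eeg_report.accuracy,
    }
    reports[("eeg", "none", "clean")] = eeg_report

    emg_raw = {name: s.emg for name, s in splits.items()}
    split_labels = {name: s.labels for name, s in splits.items()}

    # ----- Experiment 1: temporary (fatigue-like) attenuation -----
    if config.run_temporary and config.temporary_levels:
        clean_feats = {
            name: emg_window_features(emg_raw[name], config.window,
                                      labels=split_labels[name])
            for name in SPLITS
        }
        emg_spec_initial = dataclasses.replace(config.emg_net, seed=_child_seed(ss))
        emg_spec_final = dataclasses.replace(config.emg_net, seed=_child_seed(ss))
        emg_initial = train_decoder(clean_feats["train"], emg_spec_initial)
        emg_final = retrain_on_train_plus_validation(
            emg_spec_final, clean_feats["train"], clean_feats["validation"])
        train_hash = _hash_signal(emg_raw["train"])
        guards["temporary_train_hash_before"] = train_hash
        hashes_after = []
        for level in config.temporary_levels:
            regime = TemporaryAlteration(validation_fraction=float(level))
            altered = apply_experiment(emg_raw, regime)
            hashes_after.append(_hash_signal(altered["train"]))
            val_feats = emg_window_features(altered["validation"], config.window,
                                            labels=split_labels["validation"])
            test_feats = emg_window_features(altered["test"], config.window,
                                             labels=split_labels["test"])
            emg_val_pred, _ = predict(emg_initial, val_feats,
                                      stateful=config.stateful_prediction)
            model = FusionModel.calibrate(
                eeg_feats["validation"].labels, eeg_val_pred,
                val_feats.labels, emg_val_pred, alpha=config.fusion_alpha,
            )
            emg_test_pred, _ = predict(emg_final, test_feats,
                                       stateful=config.stateful_prediction)
            fused_pred, _ = fuse_sequence(eeg_test_pred, emg_test_pred, model)
            true3 = test_feats.labels
            reports[("emg", "temporary", level)] = score(true3, emg_test_pred, GAIT_CLASSES)
            reports[("fused", "temporary", level)] = score(true3, fused_pred, GAIT_CLASSES)
            reports[("eeg", "temporary", level)] = eeg_report
            fusion_models[("temporary", level)] = model
        guards["temporary_train_hashes_after"] = hashes_after
        guards["temporary_train_unaltered"] = all(h == train_hash for h in hashes_after)

    # ----- Experiment 2: permanent (paresis-like) channel loss + noise -----
    if config.run_permanent and config.permanent_snrs_db:
        for snr in config.permanent_snrs_db:
            regime = PermanentAlteration(target_snr_db=snr, seed=_child_seed(ss))
            altered = apply_experiment(emg_raw, regime)
            feats = {
                name: emg_window_features(altered[name], config.window,
                                          labels=split_labels[name])
                for name in SPLITS
            }
            emg_initial = train_decoder(
                feats["train"], dataclasses.replace(config.emg_net, seed=_child_seed(ss)))
            emg_val_pred, _ = predict(emg_initial, feats["validation"],
                                      stateful=config.stateful_prediction)
            model = FusionModel.calibrate(
                eeg_feats["validation"].labels, eeg_val_pred,
                feats["validation"].labels, emg_val_pred, alpha=config.fusion_alpha,
            )
            emg_final = retrain_on_train_plus_validation(
                dataclasses.replace(config.emg_net, seed=_child_seed(ss)),
                feats["train"], feats["validation"],
            )
            emg_test_pred, _ = predict(emg_final, feats["test"],
                                       stateful=config.stateful_prediction)
            fused_pred, _ = fuse_sequence(eeg_test_pred, emg_test_pred, model)
            level = "clean" if snr is None else f"{snr:g}dB"
            true3 = feats["test"].labels
            reports[("emg", "permanent", level)] = score(true3, emg_test_pred, GAIT_CLASSES)
            reports[("fused", "permanent", level)] = score(true3, fused_pred, GAIT_CLASSES)
            reports[("eeg", "permanent", level)] = eeg_report
            fusion_models[("permanent", level)] = model

    return ExperimentBundle(reports=reports, fusion_models=fusion_models,
                            guards=guards, config_seed=config.seed)
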