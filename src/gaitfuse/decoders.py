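"""Recurrent gait decoders: EEG -> {SWING, STANCE}, EMG -> {RIGHT, LEFT, STANCE}.

The EEG network stacks two LSTM layers (250 and 150 units by default); the
EMG network uses a single 150-unit layer. Both end in a fully-connected layer
and softmax emitting per-window class posteriors at the decision rate.

Feature sequences are standardized with training-set statistics stored inside
the decoder, so a test-time change of input scale (e.g. EMG attenuation) is
seen by the network exactly as the shifted, compressed distribution it is.
Training sequences are contiguous non-overlapping runs of ``sequence_length``
windows (1 s at the 100 Hz decision rate) with truncated backpropagation;
early stopping monitors the loss on a held-out trailing fraction of the
training sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .lstm import LSTMNetwork, train_network
from .preprocessing import FeatureSequence
from .signal import EEG_CLASSES, GAIT_CLASSES

__all__ = [
    "NetworkSpec",
    "TrainedDecoder",
    "train_decoder",
    "predict",
    "retrain_on_train_plus_validation",
    "save_decoder",
    "load_decoder",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyperparameters of one decoder."""

    lstm_units: tuple[int, ...]
    n_classes: int
    learning_rate: float = 1e-3
    batch_size: int = 32
    sequence_length: int = 100      # windows per training sequence (1 s at 100 Hz)
    max_epochs: int = 50
    patience: int = 10
    class_weighting: bool = False
    holdout_fraction: float = 0.1   # trailing fraction used for early stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if any(u <= 0 for u in self.lstm_units):
            raise ValueError("lstm unit counts must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")

    @classmethod
    def eeg_default(cls, **overrides) -> "NetworkSpec":
        kw = dict(lstm_units=(250, 150), n_classes=2)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def emg_default(cls, **overrides) -> "NetworkSpec":
        kw = dict(lstm_units=(150,), n_classes=3)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainedDecoder:
    spec: NetworkSpec
    net: LSTMNetwork
    classes: tuple[str, ...]
    input_mean: np.ndarray
    input_sd: np.ndarray
    history: dict = field(default_factory=dict)

    @property
    def input_size(self) -> int:
        return self.net.input_size


def _to_sequences(features: np.ndarray, labels: np.ndarray, seq_len: int):
    """Cut aligned (windows x channels) features into contiguous sequences.

    The trailing partial sequence (fewer than ``seq_len`` windows) is dropped.
    """
    n_seq = features.shape[0] // seq_len
    if n_seq < 1:
        raise ValueError("not enough windows for a single training sequence")
    X = features[: n_seq * seq_len].reshape(n_seq, seq_len, features.shape[1])
    y = labels[: n_seq * seq_len].reshape(n_seq, seq_len)
    return X, y


def _standardize(features: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (features - mean) / sd


def train_decoder(features: FeatureSequence, spec: NetworkSpec,
                  labels: np.ndarray | None = None) -> TrainedDecoder:
    """Fit a decoder on a labeled feature sequence; deterministic given the seed.

    ``labels`` defaults to the per-window labels carried by ``features``.
    Every class of the decoder's class set must appear in the training labels.
    """
    if labels is None:
        labels = features.labels
    if labels is None:
        raise ValueError("training requires per-window labels")
    labels = np.asarray(labels)
    classes = features.classes or (EEG_CLASSES if spec.n_classes == 2 else GAIT_CLASSES)
    if len(classes) != spec.n_classes:
        raise ValueError("class set size must match spec.n_classes")
    present = np.unique(labels)
    if present.size < spec.n_classes:
        missing = [classes[i] for i in range(spec.n_classes) if i not in present]
        raise ValueError(f"training labels missing classes: {missing}")

    mean = features.features.mean(axis=0)
    sd = features.features.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = _standardize(features.features, mean, sd).astype(np.float32)
    Xs, ys = _to_sequences(X, labels, spec.sequence_length)

    n_val = int(round(spec.holdout_fraction * Xs.shape[0]))
    if n_val >= 1 and Xs.shape[0] - n_val >= 1:
        X_tr, y_tr = Xs[:-n_val], ys[:-n_val]
        X_val, y_val = Xs[-n_val:], ys[-n_val:]
    else:
        X_tr, y_tr, X_val, y_val = Xs, ys, None, None

    rng = np.random.default_rng(spec.seed)
    net = LSTMNetwork(X.shape[1], spec.lstm_units, spec.n_classes, rng)
    class_weights = None
    if spec.class_weighting:
        counts = np.bincount(y_tr.ravel(), minlength=spec.n_classes).astype(float)
        class_weights = counts.sum() / np.maximum(counts, 1.0) / spec.n_classes
    history = train_network(
        net, X_tr, y_tr, X_val, y_val, rng,
        learning_rate=spec.learning_rate, batch_size=spec.batch_size,
        max_epochs=spec.max_epochs, patience=spec.patience,
        class_weights=class_weights,
    )
    return TrainedDecoder(spec=spec, net=net, classes=tuple(classes),
                          input_mean=mean, input_sd=sd, history=history)


def predict(decoder: TrainedDecoder, features: FeatureSequence,
            stateful: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (predicted class codes, posterior vectors).

    Stateful mode carries the recurrent state across the whole stream (online
    emulation); stateless mode resets the state every ``sequence_length``
    windows. Both start from zero state, so the first window agrees.
    """
    if features.n_channels != decoder.input_size:
        raise ValueError("feature dimensionality does not match the decoder input size")
    X = _standardize(features.features, decoder.input_mean, decoder.input_sd)
    X = X.astype(np.float32)
    if stateful:
        probs, _ = decoder.net.predict_proba(X[None, :, :])
        probs = probs[0]
    else:
        T = decoder.spec.sequence_length
        n = X.shape[0]
        n_full = n // T
        chunks = []
        if n_full:
            P, _ = decoder.net.predict_proba(X[: n_full * T].reshape(n_full, T, -1))
            chunks.append(P.reshape(n_full * T, -1))
        if n % T:
            P, _ = decoder.net.predict_proba(X[n_full * T:][None, :, :])
            chunks.append(P[0])
        probs = np.concatenate(chunks, axis=0)
    return probs.argmax(axis=1).astype(np.int8), probs


def retrain_on_train_plus_validation(
    spec: NetworkSpec,
    train_features: FeatureSequence,
    val_features: FeatureSequence | None,
) -> TrainedDecoder:
    """Refit on the concatenation of training and validation features.

    Used after fusion calibration to maximize the data behind the final
    decoders; with an empty validation set this is exactly ``train_decoder``.
    The resulting decoder is evaluated on the test split only.
    """
    if val_features is None or val_features.n_windows == 0:
        return train_decoder(train_features, spec)
    if train_features.labels is None or val_features.labels is None:
        raise ValueError("both splits must carry per-window labels")
    merged = FeatureSequence(
        features=np.concatenate([train_features.features, val_features.features]),
        window_end_times=np.concatenate(
            [train_features.window_end_times, val_features.window_end_times]),
        source=train_features.source,
        channel_labels=train_features.channel_labels,
        labels=np.concatenate([train_features.labels, val_features.labels]),
        classes=train_features.classes,
    )
    return train_decoder(merged, spec)


def save_decoder(decoder: TrainedDecoder, path: str | Path) -> None:
    """Persist a decoder as a single .npz checkpoint."""
    payload = {f"param_{k}": v for k, v in decoder.net.params.items()}
    payload["input_mean"] = decoder.input_mean
    payload["input_sd"] = decoder.input_sd
    meta = {
        "spec": asdict(decoder.spec),
        "classes": list(decoder.classes),
        "history": decoder.history,
        "hidden_sizes": list(decoder.net.hidden_sizes),
        "input_size": decoder.net.input_size,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **payload)


def load_decoder(path: str | Path) -> TrainedDecoder:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec_kw = dict(meta["spec"])
        spec_kw["lstm_units"] = tuple(spec_kw["lstm_units"])
        spec = NetworkSpec(**spec_kw)
        net = LSTMNetwork(meta["input_size"], meta["hidden_sizes"], spec.n_classes,
                          np.random.default_rng(0))
        net.params = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        return TrainedDecoder(
            spec=spec, net=net, classes=tuple(meta["classes"]),
            input_mean=data["input_mean"], input_sd=data["input_sd"],
            history=meta["history"],
        )
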