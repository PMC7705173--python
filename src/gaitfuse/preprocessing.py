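"""Sliding-window segmentation and the EEG/EMG per-window feature pipelines.

Both modalities are cut into rectangular 50 ms windows with 80% overlap, so
features (and hence decoder decisions) are produced at 1 / (0.2 * 0.050 s) =
100 Hz. Inside each window:

* EEG: common average reference across channels, zero-phase 4th-order
  Butterworth band-pass to the delta-theta band (1-8 Hz), per-channel z-score
  within the window, then the block average of the trailing non-overlapping
  20% of the window -> one scalar per channel.
* EMG: zero-phase 8th-order Butterworth band-pass 10-250 Hz, full-wave
  rectification, zero-phase 4th-order 6 Hz low-pass envelope, then the same
  trailing block average. The EMG pipeline is positively homogeneous:
  scaling the input scales every feature by the same factor.

Zero-phase filtering is realized as forward-backward application of the
stated design order with odd-symmetric reflection padding of length
min(3 * (order + 1), window - 1); with 50-sample windows the padding choice
is consequential and therefore fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .signal import EEG_CLASSES, GAIT_CLASSES, GaitLabelSeries, MultichannelSignal, to_eeg_codes

__all__ = [
    "WindowSpec",
    "FeatureSequence",
    "segment",
    "block_average",
    "eeg_window_features",
    "emg_window_features",
    "window_labels",
    "common_average_reference",
]


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular analysis window: length, fractional overlap, trailing block."""

    window_length: float = 0.050   # s
    overlap: float = 0.8           # fraction of the window shared with the next
    block_fraction: float = 0.2    # trailing fraction summarized by block_average

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if not 0 < self.block_fraction <= 1:
            raise ValueError("block_fraction must lie in (0, 1]")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")

    @property
    def step(self) -> float:
        """Hop between consecutive windows, in seconds."""
        return self.window_length * (1.0 - self.overlap)

    @property
    def decision_rate(self) -> float:
        """Decisions per second: 1 / step."""
        return 1.0 / self.step

    def sample_counts(self, fs: float) -> tuple[int, int, int]:
        """(window, step, block) lengths in samples at rate ``fs``."""
        w = int(round(self.window_length * fs))
        s = int(round(self.step * fs))
        b = max(int(round(self.block_fraction * w)), 1)
        if w < 1 or s < 1:
            raise ValueError("window/step shorter than one sample at this rate")
        return w, s, b


@dataclass
class FeatureSequence:
    """Per-window, per-channel scalar features with timestamps and labels."""

    features: np.ndarray                 # (n_windows, n_channels)
    window_end_times: np.ndarray         # s, end of each window
    source: str                          # "EEG" | "EMG"
    channel_labels: tuple[str, ...]
    labels: np.ndarray | None = None     # per-window class codes
    classes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.window_end_times = np.asarray(self.window_end_times, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (windows x channels)")
        if self.window_end_times.size != self.features.shape[0]:
            raise ValueError("one timestamp per window required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.size != self.features.shape[0]:
                raise ValueError("one label per window required")

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    def with_labels(self, labels: np.ndarray, classes: tuple[str, ...]) -> "FeatureSequence":
        return FeatureSequence(
            features=self.features, window_end_times=self.window_end_times,
            source=self.source, channel_labels=self.channel_labels,
            labels=np.asarray(labels), classes=tuple(classes),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features, columns=list(self.channel_labels))
        df.insert(0, "time_s", self.window_end_times)
        if self.labels is not None:
            df["label"] = np.asarray(self.classes)[self.labels]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str,
                 classes: tuple[str, ...] | None = None) -> "FeatureSequence":
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            names = df.pop("label").to_numpy()
            if classes is None:
                classes = GAIT_CLASSES if "RIGHT" in set(names) else EEG_CLASSES
            lookup = {c: i for i, c in enumerate(classes)}
            labels = np.asarray([lookup[n] for n in names], dtype=np.int8)
        times = df.pop("time_s").to_numpy()
        return cls(features=df.to_numpy(), window_end_times=times, source=source,
                   channel_labels=tuple(df.columns), labels=labels, classes=classes)


def segment(signal: MultichannelSignal, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cut a signal into overlapping windows.

    Returns ``(windows, end_times)`` where ``windows`` has shape
    (n_windows, window_samples, n_channels) and is a read-only view, and
    ``end_times`` marks the end of each window in seconds. The number of
    windows is floor((N - w) / s) + 1.
    """
    w, s, _ = spec.sample_counts(signal.sampling_rate)
    if signal.n_samples < w:
        raise ValueError("signal shorter than one window")
    views = sliding_window_view(signal.samples, w, axis=0)[::s]  # (n_w, C, w)
    windows = views.transpose(0, 2, 1)
    starts = np.arange(windows.shape[0]) * s
    end_times = (starts + w) / signal.sampling_rate
    return windows, end_times


def block_average(windows: np.ndarray, block_fraction: float) -> np.ndarray:
    """Mean over the trailing block of each window.

    ``windows`` has the window-sample axis second-to-last; the block length is
    round(block_fraction * window), at least one sample.
    """
    w = windows.shape[-2]
    b = max(int(round(block_fraction * w)), 1)
    return windows[..., w - b:, :].mean(axis=-2)


def common_average_reference(windows: np.ndarray) -> np.ndarray:
    """Subtract the per-sample cross-channel mean (idempotent)."""
    if windows.shape[-1] < 2:
        raise ValueError("common average reference requires at least 2 channels")
    return windows - windows.mean(axis=-1, keepdims=True)


def _zero_phase(x: np.ndarray, order: int, Wn, btype: str, fs: float) -> np.ndarray:
    sos = sps.butter(order, Wn, btype=btype, fs=fs, output="sos")
    padlen = min(3 * (order + 1), x.shape[-2] - 1)
    return sps.sosfiltfilt(sos, x, axis=-2, padtype="odd", padlen=padlen)


def _process_eeg_windows(windows: np.ndarray, fs: float,
                         band: tuple[float, float], order: int) -> np.ndarray:
    """CAR -> zero-phase band-pass -> per-channel within-window z-score."""
    x = common_average_reference(windows)
    x = _zero_phase(x, order, band, "bandpass", fs)
    mu = x.mean(axis=-2, keepdims=True)
    sd = x.std(axis=-2, keepdims=True)
    # Degenerate (flat) channel inside a window -> zeros, not NaN. The floor
    # is relative to the raw window amplitude: a channel annihilated by CAR
    # leaves only rounding residue, which must not be z-scored up to O(1).
    scale = np.sqrt((windows**2).mean(axis=-2, keepdims=True))
    floor = 1e-9 * np.maximum(scale, np.finfo(float).tiny)
    ok = sd > floor
    return np.where(ok, (x - mu) / np.where(ok, sd, 1.0), 0.0)


def _process_emg_windows(windows: np.ndarray, fs: float, band: tuple[float, float],
                         bp_order: int, lp_cut: float, lp_order: int) -> np.ndarray:
    """Zero-phase band-pass -> rectify -> zero-phase low-pass envelope."""
    if band[1] >= fs / 2:
        raise ValueError("EMG band upper edge must be below Nyquist")
    x = _zero_phase(windows, bp_order, band, "bandpass", fs)
    x = np.abs(x)
    return _zero_phase(x, lp_order, lp_cut, "lowpass", fs)


def _chunked(process, windows: np.ndarray, spec: WindowSpec, chunk: int = 8192) -> np.ndarray:
    out = np.empty((windows.shape[0], windows.shape[2]))
    for i in range(0, windows.shape[0], chunk):
        out[i:i + chunk] = block_average(process(windows[i:i + chunk]), spec.block_fraction)
    return out


def eeg_window_features(
    eeg: MultichannelSignal,
    spec: WindowSpec = WindowSpec(),
    band: tuple[float, float] = (1.0, 8.0),
    filter_order: int = 4,
    labels: GaitLabelSeries | None = None,
) -> FeatureSequence:
    """One scalar per channel per window from the online EEG pipeline.

    If ``labels`` is given, per-window labels over the 2-class EEG set
    (SWING/STANCE) are attached.
    """
    windows, times = segment(eeg, spec)
    fs = eeg.sampling_rate
    feats = _chunked(lambda x: _process_eeg_windows(x, fs, band, filter_order), windows, spec)
    out = FeatureSequence(features=feats, window_end_times=times, source="EEG",
                          channel_labels=eeg.channel_labels)
    if labels is not None:
        out = out.with_labels(window_labels(labels, spec, EEG_CLASSES), EEG_CLASSES)
    return out


def emg_window_features(
    emg: MultichannelSignal,
    spec: WindowSpec = WindowSpec(),
    band: tuple[float, float] = (10.0, 250.0),
    bp_order: int = 8,
    lp_cut: float = 6.0,
    lp_order: int = 4,
    labels: GaitLabelSeries | None = None,
) -> FeatureSequence:
    """One scalar per channel per window from the EMG envelope pipeline."""
    windows, times = segment(emg, spec)
    fs = emg.sampling_rate
    feats = _chunked(
        lambda x: _process_emg_windows(x, fs, band, bp_order, lp_cut, lp_order),
        windows, spec,
    )
    out = FeatureSequence(features=feats, window_end_times=times, source="EMG",
                          channel_labels=emg.channel_labels)
    if labels is not None:
        out = out.with_labels(window_labels(labels, spec, GAIT_CLASSES), GAIT_CLASSES)
    return out


def window_labels(
    labels: GaitLabelSeries,
    spec: WindowSpec = WindowSpec(),
    class_set: tuple[str, ...] = GAIT_CLASSES,
) -> np.ndarray:
    """Per-window label: majority vote over the trailing block of each window.

    The vote runs over the same samples ``block_average`` summarizes, so the
    label describes the signal span the feature describes. Ties resolve to
    STANCE (ambiguity never commands a step). For the EEG class set, RIGHT and
    LEFT both count as SWING before voting.
    """
    w, s, b = spec.sample_counts(labels.sampling_rate)
    if labels.n_samples < w:
        raise ValueError("label series shorter than one window")
    codes = labels.codes
    if tuple(class_set) == tuple(EEG_CLASSES):
        codes = to_eeg_codes(codes)
        stance_code = 1
    elif tuple(class_set) == tuple(GAIT_CLASSES):
        stance_code = 2
    else:
        raise ValueError("class_set must be the 2-class EEG or 3-class gait set")
    m = len(class_set)
    blocks = sliding_window_view(codes, w)[::s][:, w - b:]  # (n_w, b)
    counts = (blocks[:, :, None] == np.arange(m)).sum(axis=1)  # (n_w, m)
    # tie preference: STANCE first, then class-set order (RIGHT before LEFT)
    pref = np.full(m, 1)
    pref[stance_code] = m + 1
    pref[:stance_code] = np.arange(stance_code, 0, -1)
    return np.argmax(counts * (m + 2) + pref, axis=1).astype(np.int8)
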