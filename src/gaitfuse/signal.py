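"""Core in-memory containers for synchronized multichannel biosignals and gait labels.

Gait phases are encoded as small integer codes into an explicit class tuple.
Two class sets are used throughout the package:

* the 3-class (EMG / fused) set ``("RIGHT", "LEFT", "STANCE")`` — swing of the
  right leg, swing of the left leg, double support;
* the 2-class (EEG) set ``("SWING", "STANCE")`` — a step is being taken with
  either leg vs. both feet on the ground.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RIGHT = "RIGHT"
LEFT = "LEFT"
STANCE = "STANCE"
SWING = "SWING"

#: Fused / EMG class set. Codes: 0=RIGHT, 1=LEFT, 2=STANCE.
GAIT_CLASSES: tuple[str, ...] = (RIGHT, LEFT, STANCE)
#: EEG class set. Codes: 0=SWING, 1=STANCE.
EEG_CLASSES: tuple[str, ...] = (SWING, STANCE)


@dataclass
class MultichannelSignal:
    """Synchronized sampled time series, shape (n_samples, n_channels)."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    units: str = "uV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x channels)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError("channel_labels must match the number of columns")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, samples: np.ndarray, **meta) -> "MultichannelSignal":
        """New signal sharing rate/labels/units, with updated samples and meta."""
        merged = dict(self.meta)
        merged.update(meta)
        return MultichannelSignal(
            samples=np.asarray(samples),
            sampling_rate=self.sampling_rate,
            channel_labels=self.channel_labels,
            units=self.units,
            meta=merged,
        )

    def select_channels(self, labels) -> "MultichannelSignal":
        labels = tuple(labels)
        idx = [self.channel_labels.index(lab) for lab in labels]
        return MultichannelSignal(
            samples=self.samples[:, idx],
            sampling_rate=self.sampling_rate,
            channel_labels=labels,
            units=self.units,
            meta=dict(self.meta),
        )

    def slice(self, start: int, stop: int) -> "MultichannelSignal":
        return self.copy_with(self.samples[start:stop])


@dataclass
class GaitLabelSeries:
    """Per-sample gait phase over the 3-class set, derived from foot-switch contacts."""

    codes: np.ndarray
    sampling_rate: float
    classes: tuple[str, ...] = GAIT_CLASSES

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise ValueError("codes must be 1-D")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(self.classes)):
            raise ValueError("label codes out of range for the class set")

    @property
    def n_samples(self) -> int:
        return self.codes.size

    def as_strings(self) -> np.ndarray:
        return np.asarray(self.classes)[self.codes]

    def fractions(self) -> dict[str, float]:
        """Fraction of samples per class name."""
        counts = np.bincount(self.codes, minlength=len(self.classes))
        return {c: counts[i] / max(self.n_samples, 1) for i, c in enumerate(self.classes)}

    def slice(self, start: int, stop: int) -> "GaitLabelSeries":
        return GaitLabelSeries(self.codes[start:stop], self.sampling_rate, self.classes)


def to_eeg_codes(codes: np.ndarray) -> np.ndarray:
    """Map 3-class gait codes to the 2-class EEG set (RIGHT/LEFT -> SWING)."""
    codes = np.asarray(codes)
    # RIGHT(0) and LEFT(1) -> SWING(0); STANCE(2) -> STANCE(1)
    return np.where(codes == 2, 1, 0).astype(np.int8)


def codes_from_strings(names, classes: tuple[str, ...]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.asarray([lookup[str(n)] for n in names], dtype=np.int8)
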