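"""Simulated EMG impairment regimes.

Two regimes mimic clinically motivated losses of EMG reliability:

* **Temporary** (fatigue-like): linear amplitude attenuation applied to the
  validation and test splits only — the decoders were calibrated on intact
  muscle activity and then the signal fades at usage time. "Attenuation of
  X%" means the retained amplitude fraction is 1 - X/100.
* **Permanent** (paresis-like): only the vastus medialis channel of each leg
  remains, the whole recording (all three splits) is attenuated to 30% of its
  amplitude, and Gaussian noise is added at a configured signal-to-noise
  ratio, since paretic muscle is characterized by low amplitude and poor SNR.

Noise calibration: per channel, the signal power is the mean squared
amplitude of the (attenuated) channel over the whole recording, and the noise
standard deviation is sigma = sqrt(P_signal / 10^(SNR_dB / 10)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import MultichannelSignal

__all__ = [
    "TemporaryAlteration",
    "PermanentAlteration",
    "attenuate",
    "add_noise_at_snr",
    "apply_experiment",
]

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class TemporaryAlteration:
    """Fatigue-like attenuation of the validation/test splits; training untouched.

    ``test_fraction`` defaults to ``validation_fraction``; setting them apart
    reproduces the robustness protocol where the usage-time attenuation
    differs by +-10% amplitude from the level the fusion was calibrated at.
    """

    validation_fraction: float = 1.0
    test_fraction: float | None = None

    def __post_init__(self) -> None:
        for f in (self.validation_fraction, self.test_fraction):
            if f is not None and not 0 < f <= 1:
                raise ValueError("retained amplitude fractions must lie in (0, 1]")

    @property
    def effective_test_fraction(self) -> float:
        return self.test_fraction if self.test_fraction is not None else self.validation_fraction


@dataclass(frozen=True)
class PermanentAlteration:
    """Paresis-like channel loss + attenuation + noise on all three splits."""

    retained_channel_pattern: str = "VM"
    retained_amplitude_fraction: float = 0.3
    target_snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.retained_amplitude_fraction <= 1:
            raise ValueError("retained_amplitude_fraction must lie in (0, 1]")


def attenuate(emg: MultichannelSignal, fraction: float) -> MultichannelSignal:
    """Scale every sample by the retained amplitude fraction in (0, 1]."""
    if not 0 < fraction <= 1:
        raise ValueError("retained amplitude fraction must lie in (0, 1]")
    prior = emg.meta.get("attenuation", 1.0)
    return emg.copy_with(emg.samples * fraction, attenuation=prior * fraction)


def add_noise_at_snr(emg: MultichannelSignal, target_snr_db: float,
                     seed: int) -> MultichannelSignal:
    """Add per-channel i.i.d. zero-mean Gaussian noise hitting a target SNR.

    SNR (dB) = 10 log10(P_signal / P_noise) with P_signal the channel's mean
    squared amplitude; sigma = sqrt(P_signal / 10^(SNR/10)).
    """
    power = np.mean(emg.samples.astype(np.float64) ** 2, axis=0)
    if np.any(power == 0):
        raise ValueError("cannot set an SNR for a zero-power channel")
    sigma = np.sqrt(power / 10.0 ** (target_snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(emg.samples.shape) * sigma
    return emg.copy_with(emg.samples + noise,
                         noise_snr_db=float(target_snr_db), noise_seed=int(seed))


def _retained_channels(emg: MultichannelSignal, pattern: str) -> tuple[str, ...]:
    kept = tuple(lab for lab in emg.channel_labels if pattern in lab)
    if not kept:
        raise ValueError(f"no channel label matches pattern {pattern!r}")
    return kept


def apply_experiment(
    splits: dict[str, MultichannelSignal],
    regime: TemporaryAlteration | PermanentAlteration,
) -> dict[str, MultichannelSignal]:
    """Apply one impairment regime to the (train, validation, test) EMG splits.

    Temporary regime: the training split is returned untouched (same array);
    validation and test are attenuated, possibly at different fractions.
    Permanent regime: channel subsetting, then attenuation, then noise, on
    every split, with split-specific noise sub-seeds.
    """
    missing = [s for s in SPLITS if s not in splits]
    if missing:
        raise ValueError(f"splits must contain {SPLITS}, missing {missing}")
    if isinstance(regime, TemporaryAlteration):
        return {
            "train": splits["train"],
            "validation": attenuate(splits["validation"], regime.validation_fraction),
            "test": attenuate(splits["test"], regime.effective_test_fraction),
        }
    if isinstance(regime, PermanentAlteration):
        out = {}
        child_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(regime.seed).spawn(len(SPLITS))
        ]
        for split, sub_seed in zip(SPLITS, child_seeds):
            sig = splits[split].select_channels(
                _retained_channels(splits[split], regime.retained_channel_pattern)
            )
            sig = attenuate(sig, regime.retained_amplitude_fraction)
            if regime.target_snr_db is not None:
                sig = add_noise_at_snr(sig, regime.target_snr_db, sub_seed)
            out[split] = sig
        return out
    raise TypeError("regime must be a TemporaryAlteration or PermanentAlteration")
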