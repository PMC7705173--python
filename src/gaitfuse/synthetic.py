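"""Synthetic treadmill-walking sessions: foot-switches, EMG, and EEG.

The generator emulates the statistical structure a gait decoder relies on,
for a subject walking at a steady cadence:

* alternating per-leg stance/swing square waves with double-support intervals
  (guaranteed whenever the per-leg stance fraction exceeds 0.5);
* per-muscle EMG activation envelopes, phase-locked to the gait cycle, riding
  on band-limited carriers plus baseline instrumentation noise;
* low-frequency (delta/theta range) EEG components locked to the stride, whose
  amplitude is modulated between swing (of either leg) and double support, on
  top of 1/f background activity. The locked component is identical for right
  and left swing, so the EEG stream carries swing-vs-stance information only.

Everything is seeded and bit-reproducible: one ``(params, seed)`` pair defines
one synthetic subject/session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal import GAIT_CLASSES, GaitLabelSeries, MultichannelSignal

__all__ = [
    "GaitCycleParams",
    "MuscleModel",
    "CorticalModel",
    "SyntheticSession",
    "simulate_footswitch",
    "simulate_emg",
    "simulate_eeg",
    "simulate_session",
    "labels_from_footswitch",
    "default_muscles",
    "save_session",
    "load_session",
]

_R, _L, _S = 0, 1, 2  # codes into GAIT_CLASSES

FOOTSWITCH_CHANNELS = ("left_heel", "left_toe", "right_heel", "right_toe")


@dataclass(frozen=True)
class GaitCycleParams:
    """Square-wave gait model: one shared cycle clock, two legs half a cycle apart.

    ``stance_fraction`` > 0.5 guarantees that the two swing intervals cannot
    overlap at ``leg_phase_offset`` = 0.5, i.e. double-support intervals exist
    twice per cycle and the model never goes airborne.
    """

    cycle_duration: float = 1.2      # s, mean stride time
    cycle_jitter_sd: float = 0.05    # s, sd of per-cycle duration
    stance_fraction: float = 0.62    # per-leg fraction of the cycle in stance
    leg_phase_offset: float = 0.5    # fraction of a cycle between the legs
    duration: float = 600.0          # s
    sampling_rate: float = 1000.0    # Hz

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")
        if not 0.5 < self.stance_fraction < 0.8:
            raise ValueError("stance_fraction must lie in (0.5, 0.8)")
        if self.cycle_jitter_sd < 0 or self.cycle_jitter_sd >= 0.2 * self.cycle_duration:
            raise ValueError("cycle_jitter_sd must be < 0.2 x cycle_duration")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self._swing_intervals_overlap():
            raise ValueError(
                "swing intervals of the two legs overlap (simultaneous flight): "
                "not a valid walking model"
            )

    def _swing_intervals_overlap(self) -> bool:
        # Dense-grid check of the two circular swing intervals.
        phase = np.arange(4096) / 4096.0
        right_swing = phase >= self.stance_fraction
        left_swing = ((phase - self.leg_phase_offset) % 1.0) >= self.stance_fraction
        return bool(np.any(right_swing & left_swing))


@dataclass(frozen=True)
class MuscleModel:
    """Phase-locked activation model of one muscle.

    Activation centers/widths are fractions of that leg's gait cycle with
    phase 0 at foot strike (stance onset). The burst envelope multiplies a
    band-limited unit-RMS carrier in ``carrier_band``.
    """

    name: str                         # "TA" | "VM" | "BF"
    side: str                         # "left" | "right"
    activation_centers: tuple[float, ...]
    activation_widths: tuple[float, ...]
    carrier_band: tuple[float, float] = (25.0, 150.0)
    burst_gain: float = 80.0          # uV
    baseline_noise_sd: float = 8.0    # uV

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(self.activation_centers) != len(self.activation_widths):
            raise ValueError("centers and widths must have equal length")
        if any(not 0 <= c < 1 for c in self.activation_centers):
            raise ValueError("activation_centers must lie in [0, 1)")
        if any(w <= 0 for w in self.activation_widths):
            raise ValueError("activation_widths must be positive")
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise ValueError("carrier_band must satisfy 0 < low < high")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.side}"


def default_muscles(
    burst_gain: float = 80.0, baseline_noise_sd: float = 8.0
) -> list[MuscleModel]:
    """Six-muscle montage (TA/VM/BF per leg) with textbook activation timing.

    TA fires during swing (dorsiflexion for foot clearance) and around foot
    strike; VM during early stance (loading response); BF in late swing
    (deceleration of the shank before foot strike).
    """
    timing = {
        "TA": ((0.80, 0.02), (0.06, 0.04)),
        "VM": ((0.05,), (0.05,)),
        "BF": ((0.92,), (0.05,)),
    }
    muscles = []
    for side in ("left", "right"):
        for name, (centers, widths) in timing.items():
            muscles.append(
                MuscleModel(
                    name=name,
                    side=side,
                    activation_centers=centers,
                    activation_widths=widths,
                    burst_gain=burst_gain,
                    baseline_noise_sd=baseline_noise_sd,
                )
            )
    return muscles


@dataclass(frozen=True)
class CorticalModel:
    """Gait-locked low-frequency EEG model over a generic montage.

    Each channel carries stride-locked harmonics (those falling inside
    ``gait_locked_band``, restricted to half-cycle-periodic harmonics so both
    legs' swings produce the same waveform) whose amplitude is
    ``locking_gain * (1 + swing_contrast)`` during swing of either leg and
    ``locking_gain`` during double support, plus 1/f background noise.
    Locking gains follow a spatial profile peaking over "central" channels.
    """

    n_channels: int = 16
    gait_locked_band: tuple[float, float] = (1.0, 8.0)
    peak_locking_gain: float = 4.0      # uV, at the central channel
    gain_profile_width: float = 3.0     # channels, sd of the spatial bump
    min_gain_fraction: float = 0.1      # floor of the profile, relative to peak
    background_noise_sd: float = 12.0   # uV
    background_exponent: float = 1.0    # spectral slope of 1/f^a background
    swing_contrast: float = 6.0         # relative amplitude increase in swing
    locking_gains: tuple[float, ...] | None = None  # explicit per-channel gains

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        lo, hi = self.gait_locked_band
        if not 0 < lo < hi:
            raise ValueError("gait_locked_band must satisfy 0 < low < high")
        gains = self.channel_gains()
        if np.any(gains < 0):
            raise ValueError("locking gains must be >= 0")
        if not np.any(gains > 0):
            raise ValueError("at least one channel must have a nonzero locking gain")

    def channel_gains(self) -> np.ndarray:
        if self.locking_gains is not None:
            gains = np.asarray(self.locking_gains, dtype=float)
            if gains.size != self.n_channels:
                raise ValueError("locking_gains length must equal n_channels")
            return gains
        idx = np.arange(self.n_channels)
        center = (self.n_channels - 1) / 2.0
        bump = np.exp(-0.5 * ((idx - center) / self.gain_profile_width) ** 2)
        bump = self.min_gain_fraction + (1 - self.min_gain_fraction) * bump
        return self.peak_locking_gain * bump


@dataclass
class SyntheticSession:
    """One synthetic walking session: all signals share rate and sample count."""

    eeg: MultichannelSignal
    emg: MultichannelSignal
    footswitch: MultichannelSignal
    labels: GaitLabelSeries
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.labels.n_samples
        for sig in (self.eeg, self.emg, self.footswitch):
            if sig.n_samples != n:
                raise ValueError("all signals must share the sample count")
            if sig.sampling_rate != self.labels.sampling_rate:
                raise ValueError("all signals must share the sampling rate")

    @property
    def sampling_rate(self) -> float:
        return self.labels.sampling_rate

    def slice(self, start: int, stop: int) -> "SyntheticSession":
        return SyntheticSession(
            eeg=self.eeg.slice(start, stop),
            emg=self.emg.slice(start, stop),
            footswitch=self.footswitch.slice(start, stop),
            labels=self.labels.slice(start, stop),
            seed=self.seed,
            params=dict(self.params),
        )


# ---------------------------------------------------------------------------
# foot-switches and labels


def _cycle_phase(params: GaitCycleParams, rng: np.random.Generator) -> np.ndarray:
    """Within-cycle phase fraction in [0, 1) for every sample.

    Cycle boundaries are placed on integer sample indices, so with zero
    jitter the phase (and everything derived from it) is exactly periodic
    with period round(cycle_duration * sampling_rate) samples.
    """
    n = int(round(params.duration * params.sampling_rate))
    fs = params.sampling_rate
    bounds = [0]
    t = 0.0
    while bounds[-1] < n:
        d = params.cycle_duration
        if params.cycle_jitter_sd > 0:
            d = rng.normal(params.cycle_duration, params.cycle_jitter_sd)
            d = max(d, 0.5 * params.cycle_duration)
        t += d
        nxt = int(round(t * fs))
        if nxt <= bounds[-1]:
            nxt = bounds[-1] + 1
        bounds.append(nxt)
    bounds = np.asarray(bounds)
    idx = np.arange(n)
    k = np.searchsorted(bounds, idx, side="right") - 1
    start = bounds[k]
    length = bounds[k + 1] - bounds[k]
    return (idx - start) / length


def labels_from_footswitch(footswitch: MultichannelSignal) -> GaitLabelSeries:
    """Derive per-sample gait phase from the 4 binary contact traces.

    Per-leg stance = (heel OR toe) contact. STANCE where both feet are down,
    RIGHT where the right foot is off, LEFT where the left foot is off.
    Samples with both feet off (possible under timing jitter; walking, not
    running) inherit the previous valid label; a leading run defaults to STANCE.
    """
    sig = footswitch.select_channels(FOOTSWITCH_CHANNELS)
    contact = sig.samples > 0.5
    left_down = contact[:, 0] | contact[:, 1]
    right_down = contact[:, 2] | contact[:, 3]
    codes = np.full(left_down.size, _S, dtype=np.int8)
    codes[~right_down & left_down] = _R
    codes[~left_down & right_down] = _L
    invalid = ~left_down & ~right_down
    if np.any(invalid):
        idx = np.arange(codes.size)
        idx[invalid] = 0
        idx = np.maximum.accumulate(idx)
        filled = codes[idx]
        filled[: np.argmax(~invalid)] = _S  # leading invalid run
        codes = np.where(invalid, filled, codes)
    return GaitLabelSeries(codes, footswitch.sampling_rate, GAIT_CLASSES)


def simulate_footswitch(
    params: GaitCycleParams, seed: int
) -> tuple[MultichannelSignal, GaitLabelSeries]:
    """Binary heel/toe contact traces for both feet, plus derived labels.

    Heel contact covers the first three quarters of stance, toe contact from
    20% of stance to toe-off; their union is exactly the stance interval.
    """
    rng = np.random.default_rng(seed)
    frac = _cycle_phase(params, rng)
    sf = params.stance_fraction

    def leg_traces(phase_frac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        heel = (phase_frac < 0.75 * sf).astype(np.float64)
        toe = ((phase_frac >= 0.20 * sf) & (phase_frac < sf)).astype(np.float64)
        return heel, toe

    right_frac = frac
    left_frac = (frac - params.leg_phase_offset) % 1.0
    rh, rt = leg_traces(right_frac)
    lh, lt = leg_traces(left_frac)
    sig = MultichannelSignal(
        samples=np.column_stack([lh, lt, rh, rt]),
        sampling_rate=params.sampling_rate,
        channel_labels=FOOTSWITCH_CHANNELS,
        units="binary",
        meta={"seed": int(seed)},
    )
    return sig, labels_from_footswitch(sig)


# ---------------------------------------------------------------------------
# EMG


def _leg_phase_from_labels(labels: GaitLabelSeries, swing_code: int) -> np.ndarray:
    """Reconstruct one leg's cycle phase in [0, 1) from its swing intervals.

    Phase 0 is placed at foot strike (swing -> stance transition); the phase
    advances linearly between consecutive strikes, extrapolating one median
    stride at both ends.
    """
    swing = labels.codes == swing_code
    strikes = np.flatnonzero(swing[:-1] & ~swing[1:]) + 1
    if strikes.size < 2:
        raise ValueError("labels contain fewer than two gait cycles for this leg")
    med = float(np.median(np.diff(strikes)))
    anchors = np.concatenate([[strikes[0] - med], strikes, [strikes[-1] + med]])
    idx = np.arange(labels.n_samples, dtype=float)
    phi = np.interp(idx, anchors, np.arange(anchors.size, dtype=float))
    return phi % 1.0


def _circular_envelope(
    phase: np.ndarray, centers, widths, gain: float
) -> np.ndarray:
    env = np.zeros_like(phase)
    for c, w in zip(centers, widths):
        d = np.abs(phase - c)
        d = np.minimum(d, 1.0 - d)  # circular distance on the cycle
        env += np.exp(-0.5 * (d / w) ** 2)
    return gain * env


def _bandlimited_carrier(
    n: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS noise carrier band-passed to ``band``."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError("carrier band upper edge must be below Nyquist")
    white = rng.standard_normal(n)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(carrier**2))
    return carrier / max(rms, 1e-30)


def simulate_emg(
    labels: GaitLabelSeries, muscles: list[MuscleModel], seed: int
) -> MultichannelSignal:
    """Surface-EMG-like traces: phase-locked burst envelopes times carriers."""
    rng = np.random.default_rng(seed)
    fs = labels.sampling_rate
    n = labels.n_samples
    phases: dict[str, np.ndarray] = {}
    channels = []
    for m in muscles:
        swing_code = _R if m.side == "right" else _L
        if m.burst_gain != 0:
            if m.side not in phases:
                phases[m.side] = _leg_phase_from_labels(labels, swing_code)
            env = _circular_envelope(
                phases[m.side], m.activation_centers, m.activation_widths, m.burst_gain
            )
            carrier = _bandlimited_carrier(n, m.carrier_band, fs, rng)
            x = env * carrier
        else:
            # keep the rng stream aligned so gain=0 only zeroes the bursts
            rng.standard_normal(n)
            x = np.zeros(n)
        x = x + rng.normal(0.0, m.baseline_noise_sd, size=n)
        channels.append(x)
    return MultichannelSignal(
        samples=np.column_stack(channels),
        sampling_rate=fs,
        channel_labels=tuple(m.label for m in muscles),
        units="uV",
        meta={"seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# EEG


def _one_over_f_noise(
    n: int, fs: float, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.maximum(freqs, 1.0) ** (exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    x_sd = np.std(x)
    return x * (sd / max(x_sd, 1e-30))


def _smooth_indicator(indicator: np.ndarray, fs: float, width_s: float = 0.1) -> np.ndarray:
    w = max(int(round(width_s * fs)) | 1, 3)  # odd length
    kernel = np.hanning(w)
    kernel /= kernel.sum()
    return np.convolve(indicator.astype(float), kernel, mode="same")


def simulate_eeg(
    labels: GaitLabelSeries, cortical: CorticalModel, seed: int
) -> MultichannelSignal:
    """EEG-like traces with a stride-locked low-frequency component.

    The locked waveform is a constant-envelope frequency-modulated carrier:
    an even stride harmonic near the center of ``gait_locked_band`` whose
    instantaneous frequency sweeps within the band twice per stride. Being
    half-cycle periodic, RIGHT and LEFT swing produce identical cortical
    signatures (the EEG stream is informative about swing vs. stance only),
    and the constant envelope keeps band power uniform over the cycle, so
    only the swing/stance amplitude contrast separates the classes.
    """
    rng = np.random.default_rng(seed)
    fs = labels.sampling_rate
    n = labels.n_samples
    phi = _leg_phase_from_labels(labels, _R)

    # stride period estimated from the reconstructed phase
    wraps = np.flatnonzero(np.diff(phi) < -0.5)
    stride_s = (
        float(np.median(np.diff(wraps))) / fs if wraps.size >= 2 else labels.n_samples / fs
    )
    f0 = 1.0 / stride_s
    lo, hi = cortical.gait_locked_band
    # even harmonic nearest the band center (half-cycle periodicity)
    k0 = 2 * max(1, round(stride_s * (lo + hi) / 4.0))
    if not lo <= k0 * f0 <= hi:
        raise ValueError(
            "no half-cycle-periodic stride harmonic falls inside gait_locked_band"
        )
    dev = 0.8 * min(k0 - lo * stride_s, hi * stride_s - k0)
    dev = max(dev, 0.0)
    waveform = np.sin(2 * np.pi * (k0 * phi + dev / (4 * np.pi) * np.sin(4 * np.pi * phi)))
    waveform /= np.sqrt(np.mean(waveform**2))

    swing = _smooth_indicator((labels.codes != _S).astype(float), fs)
    amplitude = 1.0 + cortical.swing_contrast * swing
    gains = cortical.channel_gains()
    locked = waveform * amplitude

    channels = np.empty((n, cortical.n_channels))
    for c in range(cortical.n_channels):
        background = _one_over_f_noise(
            n, fs, cortical.background_exponent, cortical.background_noise_sd, rng
        )
        channels[:, c] = gains[c] * locked + background
    labels_ch = tuple(f"ch{c + 1:02d}" for c in range(cortical.n_channels))
    return MultichannelSignal(
        samples=channels,
        sampling_rate=fs,
        channel_labels=labels_ch,
        units="uV",
        meta={"seed": int(seed), "central_channel": (cortical.n_channels - 1) // 2},
    )


# ---------------------------------------------------------------------------
# full session


def simulate_session(
    params: GaitCycleParams | None = None,
    muscles: list[MuscleModel] | None = None,
    cortical: CorticalModel | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """Generate one fully synchronized session from a single master seed."""
    params = params or GaitCycleParams()
    muscles = muscles if muscles is not None else default_muscles()
    cortical = cortical or CorticalModel()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    footswitch, labels = simulate_footswitch(params, seeds[0])
    emg = simulate_emg(labels, muscles, seeds[1])
    eeg = simulate_eeg(labels, cortical, seeds[2])
    snapshot = {
        "gait": asdict(params),
        "muscles": [asdict(m) for m in muscles],
        "cortical": asdict(cortical),
    }
    return SyntheticSession(
        eeg=eeg, emg=emg, footswitch=footswitch, labels=labels,
        seed=int(seed), params=snapshot,
    )


# ---------------------------------------------------------------------------
# persistence (HDF5 container or a directory of CSV matrices)


def save_session(session: SyntheticSession, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            for name, sig in (
                ("eeg", session.eeg), ("emg", session.emg), ("footswitch", session.footswitch)
            ):
                g = f.create_group(name)
                g.create_dataset("samples", data=sig.samples)
                g.attrs["sampling_rate"] = sig.sampling_rate
                g.attrs["channel_labels"] = json.dumps(list(sig.channel_labels))
                g.attrs["units"] = sig.units
            g = f.create_group("labels")
            g.create_dataset("codes", data=session.labels.codes)
            g.attrs["sampling_rate"] = session.labels.sampling_rate
            g.attrs["classes"] = json.dumps(list(session.labels.classes))
            meta = f.create_group("meta")
            meta.attrs["seed"] = session.seed
            meta.attrs["params"] = json.dumps(session.params)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, sig in (
            ("eeg", session.eeg), ("emg", session.emg), ("footswitch", session.footswitch)
        ):
            header = ",".join(sig.channel_labels)
            np.savetxt(path / f"{name}.csv", sig.samples, delimiter=",",
                       header=header, comments="")
            (path / f"{name}.json").write_text(json.dumps(
                {"sampling_rate": sig.sampling_rate, "units": sig.units}))
        np.savetxt(path / "labels.csv", session.labels.codes, fmt="%d")
        (path / "meta.json").write_text(json.dumps({
            "seed": session.seed,
            "params": session.params,
            "label_classes": list(session.labels.classes),
            "sampling_rate": session.labels.sampling_rate,
        }))


def load_session(path: str | Path) -> SyntheticSession:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            sigs = {}
            for name in ("eeg", "emg", "footswitch"):
                g = f[name]
                sigs[name] = MultichannelSignal(
                    samples=g["samples"][...],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    channel_labels=tuple(json.loads(g.attrs["channel_labels"])),
                    units=str(g.attrs["units"]),
                )
            labels = GaitLabelSeries(
                f["labels"]["codes"][...],
                float(f["labels"].attrs["sampling_rate"]),
                tuple(json.loads(f["labels"].attrs["classes"])),
            )
            seed = int(f["meta"].attrs["seed"])
            params = json.loads(f["meta"].attrs["params"])
    else:
        meta = json.loads((path / "meta.json").read_text())
        sigs = {}
        for name in ("eeg", "emg", "footswitch"):
            info = json.loads((path / f"{name}.json").read_text())
            with open(path / f"{name}.csv") as fh:
                header = fh.readline().strip().split(",")
            samples = np.loadtxt(path / f"{name}.csv", delimiter=",", skiprows=1, ndmin=2)
            sigs[name] = MultichannelSignal(
                samples=samples, sampling_rate=info["sampling_rate"],
                channel_labels=tuple(header), units=info["units"],
            )
        labels = GaitLabelSeries(
            np.loadtxt(path / "labels.csv", dtype=int),
            meta["sampling_rate"], tuple(meta["label_classes"]),
        )
        seed, params = meta["seed"], meta["params"]
    return SyntheticSession(
        eeg=sigs["eeg"], emg=sigs["emg"], footswitch=sigs["footswitch"],
        labels=labels, seed=seed, params=params,
    )
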