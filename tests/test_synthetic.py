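"""Synthetic gait generator: label geometry, phase locking, determinism."""

import numpy as np
import pytest

import gaitfuse as gf
from gaitfuse.signal import GAIT_CLASSES
from gaitfuse.synthetic import labels_from_footswitch


class TestFootswitch:
    def test_label_fractions_square_wave(self, jitter_free_params):
        # stance_fraction 0.6, offset 0.5, no jitter: each leg swings 40% of
        # the cycle and the two double-support intervals cover the rest.
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        frac = labels.fractions()
        assert frac["RIGHT"] == pytest.approx(0.40, abs=0.01)
        assert frac["LEFT"] == pytest.approx(0.40, abs=0.01)
        assert frac["STANCE"] == pytest.approx(0.20, abs=0.01)

    def test_near_unit_stance_fraction_is_mostly_stance(self):
        params = gf.GaitCycleParams(stance_fraction=0.79, cycle_jitter_sd=0.0,
                                    duration=10.0)
        _, labels = gf.simulate_footswitch(params, seed=0)
        assert labels.fractions()["STANCE"] > 0.5

    def test_same_seed_bit_identical(self, jitter_free_params):
        a, la = gf.simulate_footswitch(jitter_free_params, seed=7)
        b, lb = gf.simulate_footswitch(jitter_free_params, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(la.codes, lb.codes)

    def test_contact_trace_matches_stance_label(self, jitter_free_params):
        sig, labels = gf.simulate_footswitch(jitter_free_params, seed=3)
        left_down = (sig.samples[:, 0] > 0.5) | (sig.samples[:, 1] > 0.5)
        right_down = (sig.samples[:, 2] > 0.5) | (sig.samples[:, 3] > 0.5)
        # each foot's contact is 1 exactly during that foot's stance
        assert not np.any((labels.codes == 0) & right_down)   # RIGHT = right foot off
        assert not np.any((labels.codes == 1) & left_down)    # LEFT = left foot off
        assert np.all((left_down & right_down) == (labels.codes == 2))

    def test_labels_rederivable_from_footswitch(self, jitter_free_params):
        sig, labels = gf.simulate_footswitch(jitter_free_params, seed=3)
        np.testing.assert_array_equal(labels_from_footswitch(sig).codes, labels.codes)

    def test_jitter_free_labels_exactly_periodic(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=5)
        period = int(jitter_free_params.cycle_duration * jitter_free_params.sampling_rate)
        np.testing.assert_array_equal(labels.codes[:-period], labels.codes[period:])

    def test_label_conservation(self, short_session):
        counts = np.bincount(short_session.labels.codes, minlength=3)
        assert counts.sum() == short_session.labels.n_samples

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stance_fraction": 0.45},                        # no double support
            {"stance_fraction": 0.55, "leg_phase_offset": 0.1},  # simultaneous flight
            {"cycle_jitter_sd": 0.5},                         # jitter bound
            {"cycle_duration": -1.0},
        ],
    )
    def test_invalid_walking_models_rejected(self, kwargs):
        merged = {"cycle_jitter_sd": 0.0, "duration": 5.0, **kwargs}
        with pytest.raises(ValueError):
            gf.GaitCycleParams(**merged)


class TestEMG:
    def test_zero_gain_gives_pure_baseline_noise(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        muscles = [
            gf.MuscleModel(name="TA", side="right", activation_centers=(0.8,),
                           activation_widths=(0.05,), burst_gain=0.0,
                           baseline_noise_sd=5.0)
        ]
        emg = gf.simulate_emg(labels, muscles, seed=2)
        assert np.std(emg.samples[:, 0]) == pytest.approx(5.0, rel=0.05)
        assert np.mean(emg.samples[:, 0]) == pytest.approx(0.0, abs=0.5)

    def test_swing_locked_muscle_louder_in_swing(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        muscles = [
            gf.MuscleModel(name="TA", side="right", activation_centers=(0.8,),
                           activation_widths=(0.06,), burst_gain=80.0,
                           baseline_noise_sd=8.0)
        ]
        emg = gf.simulate_emg(labels, muscles, seed=2)
        rect = np.abs(emg.samples[:, 0])
        swing = labels.codes == 0  # RIGHT
        assert rect[swing].mean() > 1.5 * rect[labels.codes == 2].mean()

    def test_carrier_band_above_nyquist_rejected(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        muscles = [
            gf.MuscleModel(name="TA", side="right", activation_centers=(0.8,),
                           activation_widths=(0.05,), carrier_band=(100.0, 600.0))
        ]
        with pytest.raises(ValueError):
            gf.simulate_emg(labels, muscles, seed=0)

    def test_determinism(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        muscles = gf.default_muscles()
        a = gf.simulate_emg(labels, muscles, seed=9)
        b = gf.simulate_emg(labels, muscles, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


def _band_power_per_window(x, fs, band, win):
    """Mean 1-8 Hz band power of consecutive windows of ``win`` samples."""
    from scipy import signal as sps
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    n = (len(x) // win) * win
    return (filt[:n] ** 2).reshape(-1, win).mean(axis=1)


class TestEEG:
    def test_zero_contrast_equal_band_power(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        model = gf.CorticalModel(n_channels=4, swing_contrast=0.0,
                                 background_noise_sd=2.0)
        eeg = gf.simulate_eeg(labels, model, seed=3)
        from scipy import signal as sps
        sos = sps.butter(4, (1, 8), btype="bandpass", fs=1000, output="sos")
        filt = sps.sosfiltfilt(sos, eeg.samples[:, 1])
        swing_p = np.mean(filt[labels.codes != 2] ** 2)
        stance_p = np.mean(filt[labels.codes == 2] ** 2)
        assert swing_p == pytest.approx(stance_p, rel=0.25)

    def test_high_contrast_swing_power_dominates_per_cycle(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        model = gf.CorticalModel(n_channels=4, swing_contrast=3.0,
                                 background_noise_sd=0.5)
        eeg = gf.simulate_eeg(labels, model, seed=3)
        fs = int(jitter_free_params.sampling_rate)
        cyc = int(jitter_free_params.cycle_duration * fs)
        from scipy import signal as sps
        sos = sps.butter(4, (1, 8), btype="bandpass", fs=fs, output="sos")
        filt = sps.sosfiltfilt(sos, eeg.samples[:, 1])
        n_cycles = len(filt) // cyc
        wins = 0
        for k in range(n_cycles):
            seg = slice(k * cyc, (k + 1) * cyc)
            codes = labels.codes[seg]
            p = filt[seg] ** 2
            if p[codes != 2].mean() > p[codes == 2].mean():
                wins += 1
        assert wins / n_cycles >= 0.95

    def test_unlocked_channels_are_label_independent(self, jitter_free_params):
        _, labels = gf.simulate_footswitch(jitter_free_params, seed=1)
        gains = tuple(5.0 if c == 2 else 0.0 for c in range(4))
        model = gf.CorticalModel(n_channels=4, locking_gains=gains,
                                 background_noise_sd=3.0)
        eeg = gf.simulate_eeg(labels, model, seed=3)
        swing = labels.codes != 2
        for ch in (0, 1, 3):
            p_swing = np.mean(eeg.samples[swing, ch] ** 2)
            p_stance = np.mean(eeg.samples[~swing, ch] ** 2)
            assert p_swing == pytest.approx(p_stance, rel=0.2)
        # the locked channel, by contrast, is clearly modulated
        p_swing = np.mean(eeg.samples[swing, 2] ** 2)
        p_stance = np.mean(eeg.samples[~swing, 2] ** 2)
        assert p_swing > 1.5 * p_stance


class TestSession:
    def test_seed_determinism_end_to_end(self):
        p = gf.GaitCycleParams(duration=10.0)
        a = gf.simulate_session(p, seed=5)
        b = gf.simulate_session(p, seed=5)
        np.testing.assert_array_equal(a.eeg.samples, b.eeg.samples)
        np.testing.assert_array_equal(a.emg.samples, b.emg.samples)
        np.testing.assert_array_equal(a.labels.codes, b.labels.codes)

    def test_signals_share_rate_and_length(self, short_session):
        s = short_session
        assert s.eeg.n_samples == s.emg.n_samples == s.footswitch.n_samples
        assert s.eeg.sampling_rate == s.emg.sampling_rate == s.labels.sampling_rate

    def test_roundtrip_hdf5_and_csv(self, tmp_path):
        sess = gf.simulate_session(gf.GaitCycleParams(duration=5.0), seed=1)
        for target in (tmp_path / "sess.h5", tmp_path / "sess_dir"):
            gf.save_session(sess, target)
            back = gf.load_session(target)
            np.testing.assert_allclose(back.emg.samples, sess.emg.samples, rtol=1e-6)
            np.testing.assert_array_equal(back.labels.codes, sess.labels.codes)
            assert back.eeg.channel_labels == sess.eeg.channel_labels
            assert back.seed == sess.seed
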