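"""Bayesian belief fusion: confusion estimation, conditionals, fusion algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitfuse as gf
from gaitfuse.fusion import ConfusionMatrix, conditionals_from_confusion
from gaitfuse.signal import EEG_CLASSES, GAIT_CLASSES

R, L, S = 0, 1, 2
SWING, ST = 0, 1


def brute_force_beliefs(eeg_cond, emg_cond, prior, e_eeg, e_emg):
    """Independent evaluation of the belief product, explicit loops only.

    For each fused class i, multiply each classifier's conditional
    P(its class for i | its prediction) and the prior. The EEG classifier's
    class for RIGHT and LEFT is SWING, for STANCE it is STANCE.
    """
    eeg_class_for_fused = [SWING, SWING, ST]
    bel = []
    for i in range(3):
        b = 1.0
        b *= eeg_cond[eeg_class_for_fused[i]][e_eeg]
        b *= emg_cond[i][e_emg]
        b *= prior[i]
        bel.append(b)
    return bel


def _random_model(rng, alpha=0.0):
    eeg = rng.dirichlet(np.ones(2), size=2).T   # columns sum to 1
    emg = rng.dirichlet(np.ones(3), size=3).T
    return gf.FusionModel(eeg_conditionals=eeg, emg_conditionals=emg, alpha=alpha)


class TestConfusionEstimation:
    def test_perfect_predictions_are_diagonal(self):
        t = np.array([R, L, S, R, L, S])
        cm = gf.estimate_confusion(t, t, GAIT_CLASSES)
        np.testing.assert_array_equal(cm.counts, np.diag([2, 2, 2]))

    def test_direct_count_example(self):
        true = np.array([R, R, L, S])
        pred = np.array([R, L, L, S])
        cm = gf.estimate_confusion(true, pred, GAIT_CLASSES)
        expected = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]])
        np.testing.assert_array_equal(cm.counts, expected)

    def test_total_count_conserved(self, rng):
        t = rng.integers(0, 3, 500)
        p = rng.integers(0, 3, 500)
        assert gf.estimate_confusion(t, p, GAIT_CLASSES).n_samples == 500

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            gf.estimate_confusion([0, 5], [0, 1], GAIT_CLASSES)


class TestConditionals:
    def test_identity_counts_identity_conditionals(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int) * 10, GAIT_CLASSES)
        np.testing.assert_allclose(conditionals_from_confusion(cm, alpha=0), np.eye(3))

    def test_column_normalization(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[:, 0] = [8, 1, 1]
        counts[:, 1] = [0, 5, 0]
        counts[:, 2] = [0, 0, 5]
        cond = conditionals_from_confusion(ConfusionMatrix(counts, GAIT_CLASSES), alpha=0)
        np.testing.assert_allclose(cond[:, 0], [0.8, 0.1, 0.1])
        np.testing.assert_allclose(cond.sum(axis=0), 1.0)

    def test_zero_column_smoothed_to_uniform(self):
        counts = np.diag([5, 5, 0])
        cond = conditionals_from_confusion(ConfusionMatrix(counts, GAIT_CLASSES), alpha=1)
        np.testing.assert_allclose(cond[:, 2], [1 / 3, 1 / 3, 1 / 3])

    def test_zero_column_unsmoothed_is_undefined(self):
        counts = np.diag([5, 5, 0])
        with pytest.raises(ValueError):
            conditionals_from_confusion(ConfusionMatrix(counts, GAIT_CLASSES), alpha=0)


class TestFuse:
    def test_perfect_classifiers_stance_scenario(self):
        model = gf.FusionModel(eeg_conditionals=np.eye(2), emg_conditionals=np.eye(3),
                               alpha=0.0)
        out = gf.fuse(ST, S, model)
        np.testing.assert_allclose(out.beliefs, [0, 0, 1 / 3])
        assert out.decision_name == "STANCE"

    def test_hand_computed_example(self):
        eeg = np.array([[0.9, 0.2], [0.1, 0.8]])   # column SWING = (0.9, 0.1)
        emg = np.array([[0.7, 0.1, 0.2], [0.2, 0.8, 0.2], [0.1, 0.1, 0.6]])
        model = gf.FusionModel(eeg_conditionals=eeg, emg_conditionals=emg)
        out = gf.fuse(SWING, R, model)
        np.testing.assert_allclose(out.beliefs, [0.21, 0.06, 0.1 * 0.1 / 3])
        assert out.decision_name == "RIGHT"

    def test_uninformative_emg_symmetric_swing_beliefs(self):
        eeg = np.array([[0.95, 0.05], [0.05, 0.95]])
        emg = np.full((3, 3), 1 / 3)
        model = gf.FusionModel(eeg_conditionals=eeg, emg_conditionals=emg)
        out = gf.fuse(SWING, R, model)
        assert out.beliefs[R] == pytest.approx(out.beliefs[L])
        assert out.beliefs[R] > out.beliefs[S]
        # exact tie between RIGHT and LEFT: preference STANCE > RIGHT > LEFT
        assert out.decision_name == "RIGHT"

    def test_prediction_outside_class_set_rejected(self):
        model = _random_model(np.random.default_rng(0))
        with pytest.raises(ValueError):
            gf.fuse(2, S, model)  # EEG set has only 2 classes

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng)
        for e_eeg in (SWING, ST):
            for e_emg in (R, L, S):
                expected = brute_force_beliefs(
                    model.eeg_conditionals, model.emg_conditionals,
                    model.priors, e_eeg, e_emg)
                out = gf.fuse(e_eeg, e_emg, model)
                np.testing.assert_allclose(out.beliefs, expected, rtol=1e-12)

    def test_swing_ratio_independent_of_eeg(self, rng):
        """Bel(RIGHT)/Bel(LEFT) is forced by EMG alone (repeated-SWING mapping)."""
        emg = rng.dirichlet(np.ones(3), size=3).T
        for _ in range(20):
            eeg = rng.dirichlet(np.ones(2), size=2).T
            model = gf.FusionModel(eeg_conditionals=eeg, emg_conditionals=emg)
            for e_emg in (R, L, S):
                b = gf.fuse(SWING, e_emg, model).beliefs
                ratio = b[R] / b[L]
                assert ratio == pytest.approx(emg[R, e_emg] / emg[L, e_emg], rel=1e-9)

    def test_literal_prior_weighting_matches_under_uniform_priors(self, rng):
        base = _random_model(rng)
        literal = gf.FusionModel(
            eeg_conditionals=base.eeg_conditionals,
            emg_conditionals=base.emg_conditionals,
            literal_prior_weighting=True)
        for e_eeg in (SWING, ST):
            for e_emg in (R, L, S):
                a = gf.fuse(e_eeg, e_emg, base)
                b = gf.fuse(e_eeg, e_emg, literal)
                # uniform priors: same beliefs up to a constant, same decision
                np.testing.assert_allclose(b.beliefs, a.beliefs * 9.0, rtol=1e-12)
                assert a.decision == b.decision


class TestFuseSequence:
    def test_identity_emg_conditionals_pass_emg_through(self, rng):
        eeg_cond = rng.dirichlet(np.ones(2), size=2).T
        model = gf.FusionModel(eeg_conditionals=eeg_cond, emg_conditionals=np.eye(3))
        emg_pred = rng.integers(0, 3, 200)
        eeg_pred = rng.integers(0, 2, 200)
        fused, _ = gf.fuse_sequence(eeg_pred, emg_pred, model)
        np.testing.assert_array_equal(fused, emg_pred)

    def test_constant_stance_inputs_constant_output(self):
        model = _random_model(np.random.default_rng(1), alpha=1.0)
        fused, _ = gf.fuse_sequence(np.full(50, ST), np.full(50, S), model)
        assert np.unique(fused).size == 1

    def test_right_left_relabeling_equivariance(self, rng):
        model = _random_model(rng)
        swap = np.array([L, R, S])
        emg_swapped = model.emg_conditionals[swap][:, swap]
        model_swapped = gf.FusionModel(eeg_conditionals=model.eeg_conditionals,
                                       emg_conditionals=emg_swapped,
                                       tie_order=("STANCE", "LEFT", "RIGHT"))
        eeg_pred = rng.integers(0, 2, 300)
        emg_pred = rng.integers(0, 3, 300)
        fused, _ = gf.fuse_sequence(eeg_pred, emg_pred, model)
        fused_sw, _ = gf.fuse_sequence(eeg_pred, swap[emg_pred], model_swapped)
        np.testing.assert_array_equal(swap[fused], fused_sw)

    def test_belief_rescaling_never_changes_decisions(self, rng):
        model = _random_model(rng)
        eeg_pred = rng.integers(0, 2, 100)
        emg_pred = rng.integers(0, 3, 100)
        fused, beliefs = gf.fuse_sequence(eeg_pred, emg_pred, model)
        np.testing.assert_array_equal(fused, np.asarray([
            gf.fuse(a, b, model).decision for a, b in zip(eeg_pred, emg_pred)
        ]))
        assert np.all(beliefs >= 0)

    def test_length_mismatch_rejected(self):
        model = _random_model(np.random.default_rng(0))
        with pytest.raises(ValueError):
            gf.fuse_sequence(np.zeros(5, dtype=int), np.zeros(6, dtype=int), model)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, rng):
        model = _random_model(rng, alpha=0.5)
        path = tmp_path / "fusion.json"
        model.to_json(path)
        back = gf.FusionModel.from_json(path)
        np.testing.assert_allclose(back.eeg_conditionals, model.eeg_conditionals)
        np.testing.assert_allclose(back.emg_conditionals, model.emg_conditionals)
        assert back.tie_order == model.tie_order
        assert back.alpha == model.alpha

    def test_calibrate_from_validation_predictions(self, rng):
        t2 = rng.integers(0, 2, 400)
        p2 = np.where(rng.random(400) < 0.9, t2, 1 - t2)
        t3 = rng.integers(0, 3, 400)
        p3 = np.where(rng.random(400) < 0.85, t3, (t3 + 1) % 3)
        model = gf.FusionModel.calibrate(t2, p2, t3, p3, alpha=1.0)
        np.testing.assert_allclose(model.eeg_conditionals.sum(axis=0), 1.0)
        np.testing.assert_allclose(model.emg_conditionals.sum(axis=0), 1.0)
        # a mostly-correct classifier has diagonal-dominant conditionals
        assert np.all(np.diag(model.emg_conditionals) > 0.5)
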