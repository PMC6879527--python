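"""Classifier losses, split/mask/ensemble algebra, and Grad-CAM contract."""

import numpy as np
import pytest

from pblnet.classifier import (ClassifierConfig, aux_cooccurrence_loss,
                               build_classifier, ensemble_predict, final_loss,
                               gradcam, tooth_focal_loss, vertical_split)
from pblnet.labels import (INCISOR_CANINE_INDICES, PREMOLAR_MOLAR_INDICES,
                           cooccurrence_target)
from pblnet.networks import ToothClassifier, UNet


def _sym_matrix(rng, k=16):
    m = rng.random((k, k)) + 0.05
    return (m + m.T) / 2


class TestToothFocalLoss:
    def test_gamma_zero_is_mean_bce_over_pairs(self, rng):
        pred = rng.uniform(0.05, 0.95, (3, 32))
        target = (rng.random((3, 32)) > 0.7).astype(float)
        expected = np.mean(-(target * np.log(pred)
                             + (1 - target) * np.log(1 - pred)))
        assert tooth_focal_loss(pred, target, 0.0) == \
            pytest.approx(expected, rel=1e-10)

    def test_perfect_predictions_near_zero(self):
        target = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert tooth_focal_loss(target, target, 2.0) == \
            pytest.approx(0.0, abs=1e-10)

    def test_matches_scalar_loop_oracle_with_l2(self, rng):
        pred = rng.uniform(0.1, 0.9, (2, 2))
        target = np.array([[1.0, 0.0], [1.0, 1.0]])
        w = [rng.standard_normal((3, 3))]
        lam, g = 0.7, 2.0
        acc = 0.0
        for p, y in zip(pred.ravel(), target.ravel()):
            acc += -((1 - p) ** g * y * np.log(p)
                     + p ** g * (1 - y) * np.log(1 - p))
        expected = acc / 4 + lam / (2 * 4) * float(np.sum(w[0] ** 2))
        assert tooth_focal_loss(pred, target, g, lam, w) == \
            pytest.approx(expected, rel=1e-8)


class TestAuxCooccurrenceLoss:
    def test_zero_when_scores_equal_target(self, rng):
        m = _sym_matrix(rng)
        y = (rng.random(16) > 0.6).astype(int)
        c = cooccurrence_target(y, m)
        assert aux_cooccurrence_loss(c, y, m) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_labels_reduce_to_score_energy(self, rng):
        m = _sym_matrix(rng)
        pred = rng.random(16)
        assert aux_cooccurrence_loss(pred, np.zeros(16, dtype=int), m) == \
            pytest.approx(float(np.sum(pred ** 2)), rel=1e-10)

    def test_matches_term_by_term_oracle(self, rng):
        m = _sym_matrix(rng)
        y = (rng.random(16) > 0.5).astype(int)
        pred = rng.random(16)
        raw = np.array([sum(y[k] * m[j, k] for k in range(16))
                        for j in range(16)])
        z = raw.max()
        c = raw / z if z > 0 else raw
        expected = sum((c[j] - pred[j]) ** 2 for j in range(16))
        assert aux_cooccurrence_loss(pred, y, m) == \
            pytest.approx(expected, rel=1e-10)


class TestFinalLoss:
    def test_beta_zero_equals_focal_alone(self, rng):
        pred = rng.uniform(0.1, 0.9, (2, 32))
        target = (rng.random((2, 32)) > 0.6).astype(float)
        cfg = ClassifierConfig(beta=0.0, lambda_l2=0.0)
        cu, cl = _sym_matrix(rng), _sym_matrix(rng)
        assert final_loss(pred, target, cu, cl, cfg) == \
            pytest.approx(tooth_focal_loss(pred, target, cfg.gamma),
                          rel=1e-12)

    def test_composes_independent_components(self, rng):
        pred = rng.uniform(0.1, 0.9, (1, 32))
        target = (rng.random((1, 32)) > 0.5).astype(float)
        cu, cl = _sym_matrix(rng), _sym_matrix(rng)
        cfg = ClassifierConfig(beta=0.01, lambda_l2=0.0)
        expected = tooth_focal_loss(pred, target, cfg.gamma) + cfg.beta * (
            aux_cooccurrence_loss(pred[:, :16], target[:, :16], cu)
            + aux_cooccurrence_loss(pred[:, 16:], target[:, 16:], cl))
        assert final_loss(pred, target, cu, cl, cfg) == \
            pytest.approx(expected, rel=1e-10)

    def test_continuous_in_beta(self, rng):
        pred = rng.uniform(0.1, 0.9, (1, 32))
        target = (rng.random((1, 32)) > 0.5).astype(float)
        cu, cl = _sym_matrix(rng), _sym_matrix(rng)
        l0 = final_loss(pred, target, cu, cl,
                        ClassifierConfig(beta=0.0, lambda_l2=0.0))
        leps = final_loss(pred, target, cu, cl,
                          ClassifierConfig(beta=1e-6, lambda_l2=0.0))
        assert leps == pytest.approx(l0, abs=1e-4)


class TestVerticalSplit:
    def test_partition_reconstructs_input(self, rng):
        img = rng.random((8, 12))
        left, right = vertical_split(img)
        np.testing.assert_array_equal(np.concatenate([left, right], axis=-1),
                                      img)

    def test_ramp_halves_are_column_slices(self):
        img = np.tile(np.arange(8.0), (4, 1))
        left, right = vertical_split(img)
        np.testing.assert_array_equal(left, img[:, :4])
        np.testing.assert_array_equal(right, img[:, 4:])

    def test_doubles_effective_sample_count(self, rng):
        batch = rng.random((5, 8, 12))
        left, right = vertical_split(batch)
        stacked = np.concatenate([left, right])
        assert stacked.shape[0] == 2 * batch.shape[0]

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            vertical_split(np.zeros((4, 7)))


class TestBuildClassifier:
    def test_output_is_32_scores(self, rng):
        cfg = ClassifierConfig(base_channels=4, depth=2)
        model = build_classifier(None, cfg, (16, 32), seed=0)
        out = model.predict(rng.random((3, 16, 32)))
        assert out.shape == (3, 32)
        assert out.min() > 0 and out.max() < 1

    def test_random_init_same_architecture_different_weights(self, rng):
        cfg = ClassifierConfig(base_channels=4, depth=2)
        seg = UNet(in_ch=1, base=4, depth=2, rng=rng)
        transferred = build_classifier(seg.encoder_state(), cfg, (16, 32))
        random = build_classifier(None, cfg, (16, 32))
        names_t = [n for n, _ in transferred.named_parameters()]
        names_r = [n for n, _ in random.named_parameters()]
        assert names_t == names_r
        enc_t = transferred.encoder_state()
        enc_r = random.encoder_state()
        assert any(not np.array_equal(enc_t[k], enc_r[k]) for k in enc_t)

    def test_encoder_round_trip_lossless(self, rng):
        cfg = ClassifierConfig(base_channels=4, depth=2)
        seg = UNet(in_ch=1, base=4, depth=2, rng=rng)
        state = seg.encoder_state()
        model = build_classifier(state, cfg, (16, 32))
        out = model.encoder_state()
        for k in state:
            np.testing.assert_array_equal(
                out[k], np.asarray(state[k], dtype=out[k].dtype))


class TestEnsemble:
    @staticmethod
    def _stub(scores):
        class Stub:
            def __init__(self, s):
                self._s = np.asarray(s, dtype=float)

            def predict(self, images):
                return np.tile(self._s, (len(images), 1))

        return Stub(scores)

    def test_alpha_one_equals_generalist(self, rng):
        sa = rng.random(32)
        sb = rng.random(32)
        out = ensemble_predict(self._stub(sa), self._stub(sb),
                               rng.random((8, 16)), alpha=1.0)
        np.testing.assert_allclose(out, sa, rtol=1e-12)

    def test_molar_hand_example(self):
        sa = np.full(32, 0.8)
        sb = np.full(32, 0.6)
        out = ensemble_predict(self._stub(sa), self._stub(sb),
                               np.zeros((8, 16)), alpha=0.1)
        j_molar = PREMOLAR_MOLAR_INDICES[-1]
        assert out[j_molar] == pytest.approx(0.1 * 0.8 + 0.9 * 0.6)
        assert out[j_molar] == pytest.approx(0.62)

    def test_incisor_scores_ignore_specialist(self, rng):
        sa = rng.random(32)
        out1 = ensemble_predict(self._stub(sa), self._stub(np.zeros(32)),
                                rng.random((8, 16)), alpha=0.3)
        out2 = ensemble_predict(self._stub(sa), self._stub(np.ones(32)),
                                rng.random((8, 16)), alpha=0.3)
        np.testing.assert_allclose(out1[INCISOR_CANINE_INDICES],
                                   out2[INCISOR_CANINE_INDICES])

    def test_convex_combination_bounds(self, rng):
        sa, sb = rng.random(32), rng.random(32)
        out = ensemble_predict(self._stub(sa), self._stub(sb),
                               rng.random((8, 16)), alpha=0.37)
        for j in PREMOLAR_MOLAR_INDICES:
            assert min(sa[j], sb[j]) - 1e-12 <= out[j] <= \
                max(sa[j], sb[j]) + 1e-12

    def test_alpha_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_predict(self._stub(np.ones(32)),
                             self._stub(np.ones(32)),
                             rng.random((8, 16)), alpha=1.5)


class TestGradCam:
    def test_contract_shape_and_range(self, rng):
        model = ToothClassifier(base=4, depth=2, rng=rng)
        crop = rng.random((16, 32))
        cam = gradcam(model, crop, 5)
        assert cam.shape == crop.shape
        assert cam.min() >= 0.0 and cam.max() <= 1.0 + 1e-6

    def test_different_teeth_give_different_maps(self, rng):
        model = ToothClassifier(base=4, depth=2, rng=rng)
        crop = rng.random((16, 32))
        cam_a = gradcam(model, crop, 0)
        cam_b = gradcam(model, crop, 20)
        assert not np.allclose(cam_a, cam_b)

    def test_invalid_tooth_rejected(self, rng):
        model = ToothClassifier(base=4, depth=2, rng=rng)
        with pytest.raises(ValueError):
            gradcam(model, rng.random((16, 32)), 32)
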