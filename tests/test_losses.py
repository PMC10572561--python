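"""Loss functions against independent loop-based oracles and closed forms."""

import math

import numpy as np
import pytest

from petgan import engine as E
from petgan.engine import Tensor
from petgan.errors import ConfigError
from petgan.features import IdentityFeatureExtractor, SmallConvFeatureExtractor
from petgan.losses import (LOSS_NAMES, LossConfig, LossWeights, content_loss,
                           gan_loss_d, gan_loss_g, gram_matrix, l1_loss,
                           lsgan_loss_d, lsgan_loss_g, make_loss_config,
                           perceptual_loss, style_loss, total_generator_loss,
                           wgan_gp_loss_d, wgan_loss_g)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestVanillaGan:
    def test_uninformative_scores_give_two_log_two(self):
        scores = np.zeros((2, 1, 3, 3))
        assert gan_loss_d(scores, scores).item() == pytest.approx(
            2 * math.log(2), rel=1e-12)

    def test_perfect_discriminator_near_zero(self):
        real = np.full((2, 1, 2, 2), 30.0)   # σ ≈ 1
        fake = np.full((2, 1, 2, 2), -30.0)  # σ ≈ 0
        assert gan_loss_d(real, fake).item() < 1e-10

    def test_matches_elementwise_bce_oracle(self, rng):
        real = rng.normal(size=(2, 3, 3))
        fake = rng.normal(size=(2, 3, 3))
        expected = (-np.log(sigmoid(real)).mean()
                    - np.log(1 - sigmoid(fake)).mean())
        assert gan_loss_d(real, fake).item() == pytest.approx(expected,
                                                              abs=1e-6)

    def test_generator_saturating_and_not(self, rng):
        fake = rng.normal(size=(4, 2, 2))
        sat = np.log(1 - sigmoid(fake)).mean()
        nonsat = -np.log(sigmoid(fake)).mean()
        assert gan_loss_g(fake).item() == pytest.approx(sat, abs=1e-6)
        assert gan_loss_g(fake, saturating=False).item() == pytest.approx(
            nonsat, abs=1e-6)

    def test_empty_batch_rejected(self):
        with pytest.raises(ConfigError):
            gan_loss_d(np.zeros((0, 2)), np.zeros((0, 2)))


class TestLsgan:
    def test_target_values_zero_loss(self):
        ones, zeros = np.ones((2, 2)), np.zeros((2, 2))
        assert lsgan_loss_d(ones, zeros).item() == 0.0
        assert lsgan_loss_g(ones).item() == 0.0

    def test_fake_scored_zero_costs_half(self):
        assert lsgan_loss_g(np.zeros((3, 3))).item() == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        real = rng.normal(size=(2, 3, 3))
        fake = rng.normal(size=(2, 3, 3))
        expected = 0.5 * np.mean([f ** 2 for f in fake.ravel()]) \
            + 0.5 * np.mean([(r - 1) ** 2 for r in real.ravel()])
        assert lsgan_loss_d(real, fake).item() == pytest.approx(expected,
                                                                abs=1e-6)


class TestWganGp:
    def _linear_critic(self, w):
        wt = Tensor(w.reshape(1, 1, *w.shape), requires_grad=True)
        return wt, lambda x: E.conv2d(x, wt)

    def test_unit_slope_critic_has_zero_penalty(self, rng):
        w = np.zeros((2, 2))
        w[0, 0] = 1.0
        _, D = self._linear_critic(w)
        real = Tensor(rng.normal(size=(3, 1, 2, 2)))
        fake = Tensor(rng.normal(size=(3, 1, 2, 2)))
        _, comps = wgan_gp_loss_d(D, real, fake, lambda_gp=10.0, rng=rng)
        assert comps["gradient_penalty"].item() == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_slope_three_penalty_is_forty(self, rng):
        w = np.zeros((2, 2))
        w[0, 0] = 3.0
        _, D = self._linear_critic(w)
        real = Tensor(rng.normal(size=(3, 1, 2, 2)))
        fake = Tensor(rng.normal(size=(3, 1, 2, 2)))
        total, comps = wgan_gp_loss_d(D, real, fake, lambda_gp=10.0, rng=rng)
        assert comps["gradient_penalty"].item() == pytest.approx(40.0)

    def test_identical_batches_have_zero_wasserstein_term(self, rng):
        w = rng.normal(size=(2, 2))
        _, D = self._linear_critic(w)
        batch = Tensor(rng.normal(size=(4, 1, 2, 2)))
        _, comps = wgan_gp_loss_d(D, batch, batch, lambda_gp=10.0, rng=rng)
        assert comps["wasserstein"].item() == pytest.approx(0.0, abs=1e-12)

    def test_negative_lambda_rejected(self, rng):
        _, D = self._linear_critic(np.ones((2, 2)))
        x = Tensor(rng.normal(size=(1, 1, 2, 2)))
        with pytest.raises(ConfigError):
            wgan_gp_loss_d(D, x, x, lambda_gp=-1.0, rng=rng)

    def test_generator_term_is_negative_mean_score(self, rng):
        scores = rng.normal(size=(3, 4))
        assert wgan_loss_g(scores).item() == pytest.approx(-scores.mean())


class TestL1:
    def test_zero_at_identity(self, rng):
        x = rng.normal(size=(4, 4))
        assert l1_loss(x, x).item() == 0.0

    def test_constant_images(self):
        a = np.full((3, 3), 0.2)
        b = np.full((3, 3), -0.3)
        assert l1_loss(a, b).item() == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self, rng):
        a, b = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        acc = 0.0
        for i in range(4):
            for j in range(4):
                acc += abs(a[i, j] - b[i, j])
        assert l1_loss(a, b).item() == pytest.approx(acc / 16, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestGram:
    def test_single_channel_of_ones(self):
        f = np.ones((1, 2, 2))
        np.testing.assert_allclose(gram_matrix(Tensor(f)).data, [[1.0]])

    def test_symmetry(self, rng):
        f = rng.normal(size=(4, 3, 3))
        g = gram_matrix(Tensor(f)).data
        np.testing.assert_allclose(g, g.T, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        c, h, w = 3, 2, 2
        f = rng.normal(size=(c, h, w))
        expected = np.zeros((c, c))
        for i in range(c):
            for j in range(c):
                for y in range(h):
                    for x in range(w):
                        expected[i, j] += f[i, y, x] * f[j, y, x]
        expected /= c * h * w
        np.testing.assert_allclose(gram_matrix(Tensor(f)).data, expected,
                                   atol=1e-10)


class TestPerceptual:
    def setup_method(self):
        self.ident = IdentityFeatureExtractor()

    def test_content_zero_at_identity(self, rng):
        x = rng.normal(size=(1, 2, 2))
        assert content_loss(x, x, self.ident).item() == 0.0

    def test_content_constant_shift_hand_value(self):
        a = np.zeros((1, 2, 2))
        b = np.full((1, 2, 2), 0.1)
        # (1/4)·4·0.01 = 0.01
        assert content_loss(a, b, self.ident).item() == pytest.approx(0.01)

    def test_content_linear_in_weights(self, rng):
        a, b = rng.normal(size=(1, 2, 2)), rng.normal(size=(1, 2, 2))
        one = content_loss(a, b, self.ident, w_content=[1.0]).item()
        two = content_loss(a, b, self.ident, w_content=[2.0]).item()
        assert two == pytest.approx(2 * one)

    def test_style_matches_gram_oracle(self, rng):
        a, b = rng.normal(size=(2, 2, 2)), rng.normal(size=(2, 2, 2))

        def gram(f):
            g = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    g[i, j] = (f[i] * f[j]).sum()
            return g / 8.0

        expected = ((gram(a) - gram(b)) ** 2).sum()
        assert style_loss(a, b, self.ident).item() == pytest.approx(
            expected, abs=1e-10)

    def test_style_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(2, 2, 2)), rng.normal(size=(2, 2, 2))
        assert style_loss(a, b, self.ident).item() == pytest.approx(
            style_loss(b, a, self.ident).item())

    def test_degenerate_weights_select_components(self, rng):
        a, b = rng.normal(size=(1, 2, 2)), rng.normal(size=(1, 2, 2))
        c = content_loss(a, b, self.ident).item()
        s = style_loss(a, b, self.ident).item()
        assert perceptual_loss(a, b, self.ident, alpha=1, beta=0).item() \
            == pytest.approx(c)
        assert perceptual_loss(a, b, self.ident, alpha=0, beta=1).item() \
            == pytest.approx(s)
        assert perceptual_loss(a, b, self.ident, alpha=1, beta=1).item() \
            == pytest.approx(c + s)

    def test_deep_extractor_is_deterministic(self, rng):
        ex = SmallConvFeatureExtractor()
        ex2 = SmallConvFeatureExtractor()
        img = rng.normal(size=(8, 8))
        f1 = ex.extract(img)
        f2 = ex2.extract(img)
        assert len(f1) == 3
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.data, b.data)


class TestTotalObjective:
    def test_l1_weighting(self):
        cfg = make_loss_config("lsgan+l1")
        assert total_generator_loss(cfg, 0.5, 0.01).item() == pytest.approx(
            2.5)

    def test_perceptual_weighting(self):
        cfg = make_loss_config("lsgan+perceptual")
        assert total_generator_loss(cfg, 0.5, 0.2).item() == pytest.approx(
            0.52)

    def test_zero_similarity_weight(self):
        cfg = make_loss_config("gan+l1")
        cfg.weights.lambda_l1 = 0.0
        assert total_generator_loss(cfg, 0.37, 123.0).item() \
            == pytest.approx(0.37)


class TestLossConfig:
    def test_registry_contains_six_combinations(self):
        assert len(LOSS_NAMES) == 6
        for name in LOSS_NAMES:
            cfg = make_loss_config(name)
            assert cfg.name == name
            assert cfg.weights.lambda_l1 == 200.0
            assert cfg.weights.lambda_perceptual == 0.1
            assert cfg.weights.lambda_gp == 10.0
            assert cfg.weights.alpha == 1.0 and cfg.weights.beta == 1.0

    def test_unknown_combination_lists_valid_names(self):
        with pytest.raises(ConfigError, match="lsgan\\+perceptual"):
            make_loss_config("wgan+l2")

    def test_negative_weight_rejected(self):
        w = LossWeights(lambda_l1=-1.0)
        with pytest.raises(ConfigError):
            w.validate()

    def test_lambda_sim_selected_by_similarity(self):
        assert make_loss_config("gan+l1").lambda_sim == 200.0
        assert make_loss_config("gan+perceptual").lambda_sim == 0.1
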