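"""Architecture contracts and value functions of the adversarial model."""

import math

import numpy as np
import pytest

from conftest import TINY_DISC, TINY_GEN, TINY_L
from ecgan import nn
from ecgan.errors import ConfigError, ShapeError
from ecgan.gan import (DiscriminatorConfig, GeneratorConfig, LossWeights,
                       build_discriminator, build_generator,
                       discriminator_loss, discriminator_loss_grads,
                       generator_loss, generator_loss_grads, load_generator,
                       reconstruction_penalties, save_generator)


class TestGeneratorConfig:
    def test_unsupported_activation_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(activation="gelu")

    def test_inconsistent_upsampling_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(seed_length=16)  # 16 * 2^5 = 512 != 1024

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(family="transformer")

    def test_default_matches_flagship_architecture(self):
        cfg = GeneratorConfig()
        assert cfg.block_filters == (128, 64, 40, 20, 40)
        assert (cfg.seed_length, cfg.seed_channels) == (32, 256)
        assert (cfg.kernel_size, cfg.stride, cfg.dropout_rate) == (16, 2, 0.5)


@pytest.mark.parametrize("family", ["lstm_dcgan", "dcgan", "lstm_gan",
                                    "dnn_gan", "fcn_dae"])
def test_every_family_maps_fragments_to_fragments(family):
    cfg = GeneratorConfig(family=family, fragment_length=TINY_L,
                          seed_length=2, seed_channels=8,
                          block_filters=(8, 8, 8, 8, 8))
    gen = build_generator(cfg, seed=0)
    for batch in (1, 3):
        x = np.random.default_rng(batch).standard_normal((batch, TINY_L))
        assert gen.denoise_batch(x).shape == (batch, TINY_L)


def test_default_generator_upsamples_32_to_1024_through_doublings():
    gen = build_generator(GeneratorConfig(), seed=0)
    x = np.random.default_rng(0).standard_normal((1, 1024))
    lengths = []
    h = x
    for layer in gen.net:
        h = layer.forward(h, training=False)
        if isinstance(layer, nn.ConvTranspose1d):
            lengths.append(h.shape[1])
    assert lengths == [64, 128, 256, 512, 1024, 1024]  # last is the 1x1 head
    assert h.shape == (1, 1024)


def test_lstm_blocks_add_parameters_over_conv_only():
    kw = dict(fragment_length=TINY_L, seed_length=2, seed_channels=8,
              block_filters=(8, 8, 8, 8, 8))
    with_lstm = build_generator(GeneratorConfig(family="lstm_dcgan", **kw))
    conv_only = build_generator(GeneratorConfig(family="dcgan", **kw))
    assert with_lstm.n_params() > conv_only.n_params()


def test_generator_build_is_seed_deterministic():
    a = build_generator(TINY_GEN, seed=9)
    b = build_generator(TINY_GEN, seed=9)
    x = np.random.default_rng(0).standard_normal((2, TINY_L))
    assert np.array_equal(a.denoise_batch(x), b.denoise_batch(x))


class TestDiscriminator:
    def test_outputs_probabilities_summing_to_one(self):
        disc = build_discriminator(TINY_DISC, TINY_L, seed=0)
        x = np.random.default_rng(0).standard_normal((5, TINY_L))
        probs = disc.predict_proba(x)
        assert probs.shape == (5, 2)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        p = disc.prob_real(x)
        assert p.shape == (5,)

    def test_batch_size_preserved(self):
        disc = build_discriminator(TINY_DISC, TINY_L, seed=0)
        for b in (1, 7):
            x = np.zeros((b, TINY_L))
            assert disc.prob_real(x).shape == (b,)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigError):
            DiscriminatorConfig(lstm_units=0)
        with pytest.raises(ConfigError):
            build_discriminator(TINY_DISC, fragment_length=4)


class TestGeneratorLoss:
    def test_zero_residual_leaves_adversarial_term_alone(self):
        scores = np.array([0.5, 0.5])
        x = np.random.default_rng(0).standard_normal((2, 8))
        loss = generator_loss(scores, x, x)
        assert loss == pytest.approx(-math.log(0.5))

    def test_default_weights(self):
        w = LossWeights()
        assert (w.lambda_dist, w.lambda_max) == (0.7, 0.2)

    def test_penalties_match_loop_oracle(self):
        resid = np.array([[0.1, -0.2, 0.3, 0.0]])
        clean = np.zeros((1, 4))
        l_dist, l_max = reconstruction_penalties(resid, clean)
        # loop oracle: sum of squares and max abs, element by element
        s = m = 0.0
        for v in resid[0]:
            s += v * v
            m = max(m, abs(v))
        assert l_dist[0] == pytest.approx(s, abs=1e-15) == pytest.approx(0.14)
        assert l_max[0] == pytest.approx(m, abs=1e-15) == pytest.approx(0.3)

    def test_literal_and_non_saturating_modes_differ(self):
        scores = np.array([0.3])
        x = np.zeros((1, 4))
        ns = generator_loss(scores, x, x, adversarial="non_saturating")
        lit = generator_loss(scores, x, x, adversarial="literal")
        assert ns == pytest.approx(-math.log(0.3))
        assert lit == pytest.approx(math.log(0.7))

    def test_grads_match_finite_differences(self, rng):
        scores = rng.uniform(0.1, 0.9, size=3)
        clean = rng.standard_normal((3, 6))
        den = clean + rng.standard_normal((3, 6))
        w = LossWeights(0.7, 0.2)
        d_score, d_den = generator_loss_grads(scores, den, clean, w)
        eps = 1e-7
        for b in range(3):
            scores[b] += eps
            lp = generator_loss(scores, den, clean, w)
            scores[b] -= 2 * eps
            lm = generator_loss(scores, den, clean, w)
            scores[b] += eps
            assert d_score[b] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)
        for idx in [(0, 1), (1, 4), (2, 0)]:
            den[idx] += eps
            lp = generator_loss(scores, den, clean, w)
            den[idx] -= 2 * eps
            lm = generator_loss(scores, den, clean, w)
            den[idx] += eps
            assert d_den[idx] == pytest.approx((lp - lm) / (2 * eps),
                                               rel=1e-4, abs=1e-9)

    def test_boundary_scores_clamped_not_raised(self):
        loss = generator_loss(np.array([0.0, 1.0]), np.zeros((2, 4)),
                              np.zeros((2, 4)))
        assert np.isfinite(loss)


class TestDiscriminatorLoss:
    def test_perfect_discrimination_drives_loss_to_zero(self):
        loss = discriminator_loss(np.array([0.999999]), np.array([1e-6]))
        assert loss < 1e-5

    def test_maximal_confusion_is_two_ln_two(self):
        loss = discriminator_loss(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert loss == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_unequal_batch_sizes_rejected(self):
        with pytest.raises(ShapeError):
            discriminator_loss(np.array([0.5, 0.5]), np.array([0.5]))

    def test_grads_match_finite_differences(self, rng):
        pc = rng.uniform(0.2, 0.8, 4)
        pf = rng.uniform(0.2, 0.8, 4)
        d_pc, d_pf = discriminator_loss_grads(pc, pf)
        eps = 1e-7
        for b in range(4):
            pc[b] += eps
            lp = discriminator_loss(pc, pf)
            pc[b] -= 2 * eps
            lm = discriminator_loss(pc, pf)
            pc[b] += eps
            assert d_pc[b] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)


def test_dist_penalty_equals_length_times_squared_rmse(rng):
    from ecgan.metrics import rmse
    clean = rng.standard_normal((1, 1024))
    den = clean + rng.standard_normal((1, 1024)) * 0.1
    l_dist, _ = reconstruction_penalties(den, clean)
    assert l_dist[0] == pytest.approx(1024 * rmse(clean[0], den[0]) ** 2,
                                      abs=1e-9)


def test_checkpoint_roundtrip_preserves_outputs(tmp_path):
    gen = build_generator(TINY_GEN, seed=3)
    x = np.random.default_rng(0).standard_normal((2, TINY_L))
    before = gen.denoise_batch(x)
    save_generator(gen, tmp_path / "model")
    restored = load_generator(tmp_path / "model")
    assert np.array_equal(restored.denoise_batch(x), before)
    assert restored.config == gen.config
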