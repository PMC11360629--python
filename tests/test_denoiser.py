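"""Loss formulas against scalar references; generator/discriminator contracts."""

import numpy as np
import pytest

from ecganoise.denoiser import (DenoiserResults, DenoisingGAN,
                                DiscriminatorSpec, GanLossConfig,
                                GeneratorSpec, TrainingConfig,
                                build_discriminator, build_generator,
                                discriminator_loss, generator_loss)
from ecganoise.errors import ArgumentError
from ecganoise.nn.tensor import Tensor

TINY_GEN = GeneratorSpec(depth=2, filters_per_level=(4, 8), kernel_size=9)
TINY_DISC = DiscriminatorSpec(layers=((4, 9, 2), (8, 9, 2)))


def scalar_d_loss(real, fake):
    """Straight-from-the-formula reference, no tensor machinery."""
    return 0.5 * np.mean((np.asarray(real) - 1) ** 2) + 0.5 * np.mean(np.asarray(fake) ** 2)


def scalar_g_loss(fake_scores, s_hat, s, a=0.7, b=0.3):
    adv = 0.5 * np.mean((np.asarray(fake_scores) - 1) ** 2)
    diff = np.asarray(s_hat) - np.asarray(s)
    l_dist = np.mean(np.sum(diff**2, axis=-1))  # summed per window, batch mean
    l_max = np.mean(np.max(np.abs(diff), axis=-1))
    return adv + a * l_dist + b * l_max, adv, l_dist, l_max


class TestLosses:
    def test_perfect_discriminator_zero_loss(self):
        loss = discriminator_loss(Tensor(np.ones(8)), Tensor(np.zeros(8)))
        assert loss.item() == pytest.approx(0.0)

    def test_maximally_fooled_discriminator(self):
        loss = discriminator_loss(Tensor(np.zeros(8)), Tensor(np.ones(8)))
        assert loss.item() == pytest.approx(1.0)

    def test_uncertain_discriminator(self):
        loss = discriminator_loss(Tensor(np.full(4, 0.5)), Tensor(np.full(4, 0.5)))
        assert loss.item() == pytest.approx(0.25)

    def test_perfect_generator_zero_loss(self, rng):
        s = Tensor(rng.normal(size=(2, 16)))
        total, adv, l_dist, l_max = generator_loss(Tensor(np.ones(2)), s, s)
        assert total.item() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_composite(self):
        s = Tensor(np.zeros((1, 3)))
        s_hat = Tensor(np.array([[0.1, -0.3, 0.2]]))
        total, adv, l_dist, l_max = generator_loss(Tensor(np.ones(1)), s_hat, s)
        assert l_dist.item() == pytest.approx(0.14, abs=1e-6)
        assert l_max.item() == pytest.approx(0.3, abs=1e-7)
        assert total.item() == pytest.approx(0.7 * 0.14 + 0.3 * 0.3, abs=1e-6)

    def test_residual_homogeneity(self, rng):
        s = Tensor(np.zeros((3, 8)))
        d = rng.normal(size=(3, 8))
        ones = Tensor(np.ones(3))
        _, _, l1, m1 = generator_loss(ones, Tensor(d), s)
        _, _, l2, m2 = generator_loss(ones, Tensor(2 * d), s)
        assert l2.item() == pytest.approx(4 * l1.item(), rel=1e-6)
        assert m2.item() == pytest.approx(2 * m1.item(), rel=1e-6)

    def test_matches_scalar_reference_on_random_tensors(self, rng):
        for _ in range(20):
            real = rng.normal(size=6)
            fake = rng.normal(size=6)
            s = rng.normal(size=(6, 32))
            s_hat = s + rng.normal(scale=0.5, size=(6, 32))
            assert discriminator_loss(Tensor(real), Tensor(fake)).item() == \
                pytest.approx(scalar_d_loss(real, fake), abs=1e-6)
            got = generator_loss(Tensor(fake), Tensor(s_hat), Tensor(s))
            want = scalar_g_loss(fake, s_hat, s)
            for g, w in zip(got, want):
                assert g.item() == pytest.approx(w, abs=1e-6)

    def test_zero_distance_weights_reduce_to_pure_lsgan(self, rng):
        cfg = GanLossConfig(loss_weight_dist=0.0, loss_weight_max=0.0)
        fake = rng.normal(size=5)
        s = rng.normal(size=(5, 16))
        s_hat = s + rng.normal(size=(5, 16))
        total, adv, _, _ = generator_loss(Tensor(fake), Tensor(s_hat), Tensor(s), cfg)
        assert total.item() == pytest.approx(0.5 * np.mean((fake - 1) ** 2), abs=1e-7)
        assert total.item() == pytest.approx(adv.item())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            generator_loss(Tensor(np.ones(1)), Tensor(np.zeros((1, 4))),
                           Tensor(np.zeros((1, 5))))

    def test_negative_loss_weights_rejected(self):
        with pytest.raises(ArgumentError):
            GanLossConfig(loss_weight_dist=-0.1)


class TestGeneratorContracts:
    def test_output_shape_matches_input(self, rng):
        gen = build_generator(TINY_GEN, seed=0)
        x = Tensor(rng.normal(size=(3, 1, 1024)).astype(np.float32))
        assert gen(x).data.shape == (3, 1, 1024)

    def test_untrained_output_finite(self, rng):
        gen = build_generator(TINY_GEN, seed=1)
        out = gen(Tensor(rng.normal(size=(2, 1, 1024)).astype(np.float32)))
        assert np.all(np.isfinite(out.data))

    def test_zeroed_head_gives_identity_skip_path(self, rng):
        gen = build_generator(TINY_GEN, seed=2).zero_head()
        x = rng.normal(size=(2, 1, 1024)).astype(np.float32)
        out = gen(Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_input_len_not_divisible_rejected(self):
        with pytest.raises(ArgumentError):
            GeneratorSpec(input_len=1000, depth=4, filters_per_level=(4, 4, 4, 4))

    def test_same_seed_same_init(self, rng):
        a = build_generator(TINY_GEN, seed=3)
        b = build_generator(TINY_GEN, seed=3)
        x = Tensor(rng.normal(size=(1, 1, 1024)).astype(np.float32))
        np.testing.assert_array_equal(a(x).data, b(x).data)


class TestDiscriminatorContracts:
    def test_one_score_per_window(self, rng):
        disc = build_discriminator(TINY_DISC, seed=0)
        out = disc(Tensor(rng.normal(size=(5, 1, 1024)).astype(np.float32)))
        assert out.data.shape == (5, 1)
        assert np.all(np.isfinite(out.data))

    def test_deterministic_under_seed(self, rng):
        x = Tensor(rng.normal(size=(2, 1, 1024)).astype(np.float32))
        a = build_discriminator(TINY_DISC, seed=4)
        b = build_discriminator(TINY_DISC, seed=4)
        np.testing.assert_array_equal(a(x).data, b(x).data)


class TestTraining:
    @staticmethod
    def _toy_pairs(rng, n=96):
        clean = rng.normal(size=(n, 1024)) * 0.2 + 0.5
        noisy = clean + 0.3 * rng.normal(size=(n, 1024))
        return [(c, x) for c, x in zip(clean, noisy)]

    def test_distance_loss_decreases(self, rng):
        model = DenoisingGAN(self._toy_pairs(rng), TINY_GEN, TINY_DISC,
                             train_cfg=TrainingConfig(batch_size=32))
        res = model.fit(epochs=3, seed=0)
        assert res.history["L_dist"][-1] < res.history["L_dist"][0]

    def test_identical_seed_identical_history(self, rng):
        pairs = self._toy_pairs(rng, 64)
        h1 = DenoisingGAN(pairs, TINY_GEN, TINY_DISC,
                          train_cfg=TrainingConfig(batch_size=32)).fit(epochs=2, seed=5).history
        h2 = DenoisingGAN(pairs, TINY_GEN, TINY_DISC,
                          train_cfg=TrainingConfig(batch_size=32)).fit(epochs=2, seed=5).history
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ArgumentError):
            DenoisingGAN([])

    def test_denoise_shape_and_batch_invariance(self, rng):
        pairs = self._toy_pairs(rng, 64)
        res = DenoisingGAN(pairs, TINY_GEN, TINY_DISC,
                           train_cfg=TrainingConfig(batch_size=32)).fit(epochs=1, seed=0)
        noisy = np.stack([p[1] for p in pairs[:8]])
        out_all = res.denoise(noisy)
        out_small = res.denoise(noisy, batch_size=3)
        assert out_all.shape == noisy.shape
        np.testing.assert_allclose(out_all, out_small, atol=1e-6)
        single = res.denoise(noisy[0])
        np.testing.assert_allclose(single, out_all[0], atol=1e-6)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        pairs = self._toy_pairs(rng, 64)
        res = DenoisingGAN(pairs, TINY_GEN, TINY_DISC,
                           train_cfg=TrainingConfig(batch_size=32)).fit(epochs=1, seed=0)
        path = res.save(tmp_path / "den.npz")
        back = DenoiserResults.load(path)
        noisy = np.stack([p[1] for p in pairs[:4]])
        np.testing.assert_array_equal(res.denoise(noisy), back.denoise(noisy))
        assert back.history == res.history
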