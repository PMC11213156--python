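"""Latent Cycle-GAN: loss identities, imputation contracts, training."""

import numpy as np
import pytest

from neurofuse.cyclegan import (
    CycleGANPair,
    adversarial_loss,
    build_discriminator,
    build_generator,
    cycle_consistency_loss,
    evaluate_generator_mae,
    impute_latent,
    train_cyclegan,
)
from neurofuse.models import LatentVector
from neurofuse.nn import Dense, Sequential
from neurofuse.nn.layers import Layer
from tests.conftest import tiny_config


class _AffineMap(Layer):
    """y = x + c test stand-in for a generator."""

    def __init__(self, c):
        self.c = c

    def forward(self, x, train=False):
        return x + self.c

    def backward(self, gy):
        return gy

    def out_shape(self, in_shape):
        return in_shape


def _seq(*layers):
    return Sequential(list(layers))


class TestAdversarialLoss:
    def test_perfect_discriminator_zero(self):
        assert adversarial_loss(np.ones(5), np.zeros(5), side="D") == 0.0

    def test_perfect_generator_zero(self):
        assert adversarial_loss(None, np.ones(5), side="G") == 0.0

    def test_half_scores_half_loss(self):
        assert adversarial_loss(np.full(4, 0.5), np.full(4, 0.5), side="D") == pytest.approx(0.5)

    def test_bce_form_available(self):
        v = adversarial_loss(np.full(3, 10.0), np.full(3, -10.0), side="D", form="bce")
        assert v == pytest.approx(0.0, abs=1e-3)

    def test_bad_side_rejected(self):
        with pytest.raises(ValueError, match="side"):
            adversarial_loss(np.ones(2), np.ones(2), side="X")


class TestCycleConsistency:
    def test_identity_pair_zero(self):
        x = np.random.default_rng(0).normal(size=(6, 4))
        assert cycle_consistency_loss(x, _seq(_AffineMap(0.0)), _seq(_AffineMap(0.0))) == 0.0

    def test_exact_inverse_pair_zero(self):
        x = np.random.default_rng(1).normal(size=(6, 4))
        assert cycle_consistency_loss(x, _seq(_AffineMap(3.5)), _seq(_AffineMap(-3.5))) == pytest.approx(0.0)

    def test_zero_map_gives_mean_abs(self):
        x = np.random.default_rng(2).normal(size=(5, 3))
        loss = cycle_consistency_loss(x, _seq(_AffineMap(0.0)), _seq(_ZeroMap()))
        assert loss == pytest.approx(np.mean(np.abs(x)))

    def test_matches_direct_composition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 4))
        g_ab = _seq(Dense(4, 4, rng))
        g_ba = _seq(Dense(4, 4, rng))
        expected = np.mean(np.abs(g_ba.forward(g_ab.forward(x)) - x))
        assert cycle_consistency_loss(x, g_ab, g_ba) == pytest.approx(expected)

    def test_translation_pair_swap_symmetric(self):
        # for a translation pair the two cycle directions coincide, so
        # relabeling (a, b) with (G_ab, G_ba) leaves the loss unchanged
        x = np.random.default_rng(4).normal(size=(4, 4))
        g1, g2 = _seq(_AffineMap(1.0)), _seq(_AffineMap(-0.5))
        assert cycle_consistency_loss(x, g1, g2) == pytest.approx(
            cycle_consistency_loss(x, g2, g1)
        )


class _ZeroMap(Layer):
    def forward(self, x, train=False):
        return np.zeros_like(x)

    def backward(self, gy):
        return np.zeros_like(gy)

    def out_shape(self, in_shape):
        return in_shape


class TestGeneratorMAE:
    def test_perfect_generation_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        pair = CycleGANPair("smri", "fmri", _seq(_AffineMap(0.0)), _seq(_AffineMap(0.0)), None, None)
        mae = evaluate_generator_mae(pair, x, x)
        assert mae["smri->fmri"] == 0.0 and mae["fmri->smri"] == 0.0

    def test_constant_offset_gives_offset(self):
        x = np.random.default_rng(1).normal(size=(5, 4))
        pair = CycleGANPair("smri", "snp", _seq(_AffineMap(0.1)), _seq(_AffineMap(0.1)), None, None)
        mae = evaluate_generator_mae(pair, x, x)
        assert mae["smri->snp"] == pytest.approx(0.1)

    def test_hand_computed_random_case(self):
        a = np.array([[1.0, 2.0, 0.0, -1.0], [0.0, 0.0, 1.0, 1.0], [2.0, -2.0, 0.5, 0.5]])
        b = np.array([[0.0, 1.0, 1.0, -2.0], [1.0, 0.0, 0.0, 2.0], [2.0, 0.0, 0.0, 1.0]])
        pair = CycleGANPair("smri", "fmri", _seq(_AffineMap(0.0)), _seq(_AffineMap(0.0)), None, None)
        mae = evaluate_generator_mae(pair, a, b)
        # generated b_hat = a, so MAE = mean|a - b| over 12 entries
        expected = np.mean(np.abs(a - b))
        assert mae["smri->fmri"] == pytest.approx(expected)

    def test_empty_set_rejected(self):
        pair = CycleGANPair("smri", "fmri", _seq(_AffineMap(0.0)), _seq(_AffineMap(0.0)), None, None)
        with pytest.raises(ValueError, match="empty"):
            evaluate_generator_mae(pair, np.empty((0, 4)), np.empty((0, 4)))


class TestImputeLatent:
    def test_identity_generator_flags_generated(self):
        pair = CycleGANPair("smri", "fmri", _seq(_AffineMap(0.0)), _seq(_AffineMap(0.0)), None, None)
        src = LatentVector(values=np.arange(4.0), modality="smri", provenance="encoded")
        out = impute_latent(pair, src, target="fmri")
        np.testing.assert_array_equal(out.values, src.values)
        assert out.provenance == "generated" and out.source == "smri"

    def test_domain_mismatch_rejected(self):
        pair = CycleGANPair("smri", "fmri", _seq(_AffineMap(0.0)), _seq(_AffineMap(0.0)), None, None)
        src = LatentVector(values=np.zeros(4), modality="snp", provenance="encoded")
        with pytest.raises(ValueError, match="bridges"):
            impute_latent(pair, src, target="fmri")

    def test_two_layer_toy_forward_by_hand(self):
        rng = np.random.default_rng(0)
        gen = Sequential([Dense(2, 2, rng), Dense(2, 2, rng)])
        w1, b1 = gen.layers[0].w.value, gen.layers[0].b.value
        w2, b2 = gen.layers[1].w.value, gen.layers[1].b.value
        b1[:] = [0.5, -0.5]
        b2[:] = [1.0, 2.0]
        x = np.zeros((1, 2))
        expected = (x @ w1 + b1) @ w2 + b2
        np.testing.assert_allclose(gen.forward(x), expected)


class TestTraining:
    def _paired_latents(self, n=120, d=8, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, d))
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        return a, a @ q

    def test_history_length_matches_epochs(self):
        a, b = self._paired_latents()
        pair = train_cyclegan(a, b, tiny_config(epochs_cgan=4),
                              generator_hidden=(8,), discriminator_hidden=(8,), seed=5)
        assert len(pair.history) == 4
        assert [r.epoch for r in pair.history] == [0, 1, 2, 3]

    def test_determinism_same_seed_same_losses(self):
        a, b = self._paired_latents(n=40)
        cfg = tiny_config(epochs_cgan=3)
        p1 = train_cyclegan(a, b, cfg, generator_hidden=(8,), discriminator_hidden=(8,), seed=9)
        p2 = train_cyclegan(a, b, cfg, generator_hidden=(8,), discriminator_hidden=(8,), seed=9)
        h1 = [(r.d_a, r.g_ab_adv, r.cycle_a) for r in p1.history]
        h2 = [(r.d_a, r.g_ab_adv, r.cycle_a) for r in p2.history]
        assert h1 == h2
        assert p1.g_ab.checksum() == p2.g_ab.checksum()

    def test_unpaired_subjects_rejected(self):
        a, b = self._paired_latents(n=20)
        with pytest.raises(ValueError, match="unpaired"):
            train_cyclegan(a, b[:-1], tiny_config())
        with pytest.raises(ValueError, match="paired"):
            train_cyclegan(a, b, tiny_config(), subject_ids_a=["x"] * 20, subject_ids_b=["y"] * 20)

    def test_losses_logged_finite_nonnegative(self):
        a, b = self._paired_latents(n=40)
        pair = train_cyclegan(a, b, tiny_config(epochs_cgan=3),
                              generator_hidden=(8,), discriminator_hidden=(8,), seed=2)
        for r in pair.history:
            for v in (r.d_a, r.d_b, r.g_ab_adv, r.g_ba_adv, r.cycle_a, r.cycle_b):
                assert np.isfinite(v) and v >= 0

    def test_recovers_orthogonal_linear_map(self):
        """Held-out MAE < 0.15 of the latent scale on b = a Q.

        The adversarial and cycle objectives never see the pairing, so
        the map is identifiable only through distributional structure:
        the latents carry two well-separated clusters (as class-clustered
        encoder latents do), which pins the cluster correspondence and,
        with it, the linear map.
        """
        rng = np.random.default_rng(1)
        d = 16
        mu1, mu2 = rng.normal(0, 5.0, d), rng.normal(0, 5.0, d)
        a = np.vstack([
            mu1 + 0.3 * rng.normal(size=(180, d)),
            mu2 + 0.3 * rng.normal(size=(120, d)),
        ])
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        b = a @ q
        perm = np.random.default_rng(2).permutation(300)
        a, b = a[perm], b[perm]
        cfg = tiny_config(
            latent_dim=16, epochs_cgan=800, learning_rate=2e-4,
            standardize_latents=True, cycle_loss_weight=1.0,
        )
        val = np.arange(240, 300)
        pair = train_cyclegan(
            a, b, cfg, generator_hidden=(64, 128, 64), discriminator_hidden=(32, 16),
            val_indices=val, seed=4,
        )
        mae = evaluate_generator_mae(pair, a[val], b[val])
        sd = a.std()
        assert mae["smri->fmri"] < 0.15 * sd
        assert mae["fmri->smri"] < 0.15 * sd

    def test_cycle_loss_trend_decreases(self):
        a, b = self._paired_latents(n=200, d=8, seed=2)
        cfg = tiny_config(latent_dim=8, epochs_cgan=100)
        pair = train_cyclegan(a, b, cfg, generator_hidden=(32, 32), discriminator_hidden=(16,), seed=6)
        cyc = np.array([r.cycle_a + r.cycle_b for r in pair.history])
        assert cyc[-50:].mean() < cyc[:50].mean()
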