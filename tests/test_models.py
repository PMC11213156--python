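"""Encoder architectures, fusion head, and missing-modality routing."""

import numpy as np
import pytest

from neurofuse.config import RunConfig
from neurofuse.cyclegan import build_generator
from neurofuse.models import (
    FusionClassifierSpec,
    FusionModel,
    LatentVector,
    RoutingError,
    build_encoder,
    build_head,
    fuse_and_classify,
    reference_encoder_spec,
    scaled_encoder_spec,
)
from neurofuse.features import ModalityInputs
from tests.conftest import tiny_config


class TestReferenceArchitectures:
    """The reference encoder stacks, checked by symbolic shape inference —
    the full-resolution first FC layer (~10^9 weights) is never allocated."""

    @staticmethod
    def _layout(modality):
        from neurofuse.models import encoder_layout

        return encoder_layout(reference_encoder_spec(modality), RunConfig())

    def test_smri_encoder_maps_full_volume_to_latent_100(self):
        layout = self._layout("smri")
        assert layout[-1][2] == (100,)
        convs = [p for k, p, _ in layout if k == "conv"]
        assert [c["filters"] for c in convs] == [64, 64, 64, 128, 128, 128]
        assert [c["kernel"] for c in convs] == [3, 3, 3, 3, 2, 2]
        assert sum(1 for k, _, _ in layout if k == "pool") == 3
        fcs = [p for k, p, _ in layout if k == "dense"]
        assert [f["n_out"] for f in fcs] == [1536, 768, 384, 192, 100]

    def test_fmri_encoder_maps_1378_vector_to_latent_100(self):
        layout = self._layout("fmri")
        assert layout[-1][2] == (100,)
        convs = [p for k, p, _ in layout if k == "conv"]
        assert [c["filters"] for c in convs] == [64, 128, 128, 128]
        assert all(c["kernel"] == 5 for c in convs)
        assert sum(1 for k, _, _ in layout if k == "pool") == 2
        fcs = [p for k, p, _ in layout if k == "dense"]
        assert [f["n_out"] for f in fcs] == [384, 100]

    def test_snp_encoder_maps_565_dosages_to_latent_100(self):
        layout = self._layout("snp")
        assert layout[-1][2] == (100,)
        assert sum(1 for k, _, _ in layout if k == "batchnorm") == 3
        fcs = [p for k, p, _ in layout if k == "dense"]
        assert [f["n_out"] for f in fcs] == [1024, 512, 128, 100]

    def test_fusion_head_input_width_is_300(self):
        spec = FusionClassifierSpec()
        assert spec.input_width(100) == 300
        head = build_head(spec, 100, np.random.default_rng(0))
        assert head.out_shape((300,)) == (2,)


class TestScaledArchitectures:
    def test_scaled_output_dim_follows_config(self):
        cfg = tiny_config(latent_dim=16)
        for modality in ("smri", "fmri", "snp"):
            enc = build_encoder(
                modality, scaled_encoder_spec(modality, width=4, fc_width=8),
                cfg, np.random.default_rng(0),
            )
            from neurofuse.models import encoder_input_shape

            assert enc.out_shape(encoder_input_shape(modality, cfg)) == (16,)

    def test_small_grid_truncates_conv_chain(self):
        cfg = tiny_config(volume_shape=(4, 4, 4))
        enc = build_encoder(
            "smri", reference_encoder_spec("smri"), cfg, np.random.default_rng(0)
        )
        x = np.zeros((1, 1, 4, 4, 4))
        assert enc.forward(x).shape == (1, cfg.latent_dim)

    def test_forward_produces_finite_latents(self, tiny_cohort):
        cfg = tiny_config()
        inputs, _ = tiny_cohort
        enc = build_encoder(
            "smri", scaled_encoder_spec("smri", 4, 8), cfg, np.random.default_rng(1)
        )
        z = enc.forward(np.stack([inputs[0].volume])[:, None])
        assert z.shape == (1, 8) and np.all(np.isfinite(z))


class TestFuseAndClassify:
    def test_probabilities_normalized(self):
        rng = np.random.default_rng(0)
        head = build_head(FusionClassifierSpec(), 100, rng)
        latents = [rng.normal(size=100) for _ in range(3)]
        p = fuse_and_classify(latents, head)
        assert p.shape == (1, 2)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p >= 0)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        head = build_head(FusionClassifierSpec(), 10, rng)
        latents = [np.ones(10), np.zeros(10), -np.ones(10)]
        np.testing.assert_array_equal(
            fuse_and_classify(latents, head), fuse_and_classify(latents, head)
        )

    def test_mismatched_lengths_rejected(self):
        rng = np.random.default_rng(0)
        head = build_head(FusionClassifierSpec(), 10, rng)
        with pytest.raises(ValueError, match="mismatched"):
            fuse_and_classify([np.ones(10), np.ones(9), np.ones(10)], head)


def _tiny_fusion_model(cfg, with_generators=False, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    encoders = {
        m: build_encoder(m, scaled_encoder_spec(m, 4, 8), cfg, rng)
        for m in ("smri", "fmri", "snp")
    }
    head = build_head(FusionClassifierSpec(), cfg.latent_dim, rng)
    generators = None
    if with_generators:
        hidden = (8, 8)
        generators = {
            (a, b): build_generator(cfg.latent_dim, rng, hidden)
            for a, b in [("smri", "fmri"), ("fmri", "smri"), ("smri", "snp"), ("snp", "smri")]
        }
    return FusionModel(encoders, head, cfg, generators=generators)


class TestRouting:
    def test_full_mask_equals_plain_forward(self, tiny_cohort):
        cfg = tiny_config()
        inputs, _ = tiny_cohort
        model = _tiny_fusion_model(cfg, with_generators=True)
        batch = inputs[:4]
        routed, records = model.forward_routed(batch)
        plain = model.forward(batch)
        np.testing.assert_array_equal(routed, plain)
        assert all(r == {"smri": "encoded", "fmri": "encoded", "snp": "encoded"} for r in records)

    def test_missing_fmri_uses_smri_bridge(self, tiny_cohort):
        cfg = tiny_config()
        inputs, _ = tiny_cohort
        model = _tiny_fusion_model(cfg, with_generators=True)
        mi = inputs[0]
        masked = ModalityInputs(mi.subject_id, mi.class_label, mi.volume, None, mi.snp)
        logits, records = model.forward_routed([masked])
        assert records[0]["fmri"] == "generated:smri"
        assert records[0]["smri"] == "encoded"
        assert np.all(np.isfinite(logits))

    def test_only_smri_generates_both(self, tiny_cohort):
        cfg = tiny_config()
        inputs, _ = tiny_cohort
        model = _tiny_fusion_model(cfg, with_generators=True)
        mi = inputs[0]
        masked = ModalityInputs(mi.subject_id, mi.class_label, mi.volume, None, None)
        _, records = model.forward_routed([masked])
        assert records[0] == {
            "smri": "encoded", "fmri": "generated:smri", "snp": "generated:smri"
        }

    def test_missing_smri_errors_by_default(self, tiny_cohort):
        cfg = tiny_config()
        inputs, _ = tiny_cohort
        model = _tiny_fusion_model(cfg, with_generators=True)
        mi = inputs[0]
        masked = ModalityInputs(mi.subject_id, mi.class_label, None, mi.fnc, mi.snp)
        with pytest.raises(RoutingError, match="sMRI is missing"):
            model.forward_routed([masked])

    def test_chained_bridges_when_enabled(self, tiny_cohort):
        cfg = tiny_config(allow_chained_bridges=True)
        inputs, _ = tiny_cohort
        model = _tiny_fusion_model(cfg, with_generators=True)
        mi = inputs[0]
        masked = ModalityInputs(mi.subject_id, mi.class_label, None, mi.fnc, None)
        _, records = model.forward_routed([masked])
        assert records[0] == {
            "smri": "generated:fmri", "fmri": "encoded", "snp": "generated:smri"
        }

    def test_mixed_mask_batch_rejected(self, tiny_cohort):
        cfg = tiny_config()
        inputs, _ = tiny_cohort
        model = _tiny_fusion_model(cfg, with_generators=True)
        a = inputs[0]
        b = ModalityInputs("x", "AD", inputs[1].volume, None, inputs[1].snp)
        with pytest.raises(ValueError, match="uniform"):
            model.forward_routed([a, b])


class TestLatentVector:
    def test_provenance_validated(self):
        LatentVector(values=np.zeros(4), modality="fmri", provenance="generated", source="smri")
        with pytest.raises(ValueError, match="provenance"):
            LatentVector(values=np.zeros(4), modality="fmri", provenance="guessed")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            LatentVector(values=np.array([np.nan]), modality="smri", provenance="encoded")
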