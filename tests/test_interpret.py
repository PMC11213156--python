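"""Integrated Gradients, thresholding/aggregation rules, group statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse.config import RunConfig
from neurofuse.features import NetworkPartition
from neurofuse.interpret import (
    IGConfig,
    aggregate_regions,
    bonferroni,
    build_connectogram,
    group_stats,
    integrated_gradients,
    make_ig_config,
    rank_sum_test,
    select_snps,
    threshold_attributions,
    threshold_map,
)
from neurofuse.models import FusionClassifierSpec, FusionModel, build_head
from neurofuse.features import ModalityInputs
from neurofuse.nn import Dense, Flatten, ReLU, Sequential


def _linear_fusion_model(cfg: RunConfig, rng=None, hidden=False):
    """Fusion model whose encoders are flatten+linear maps.

    With ``hidden=False`` the whole network is linear in its inputs; with
    ``hidden=True`` a small ReLU head makes it a toy nonlinear MLP (kept
    small on purpose — the right-Riemann path sum converges like 1/m with
    a constant set by the number of ReLU kinks crossed along the path).
    """
    rng = rng or np.random.default_rng(0)
    n_vox = int(np.prod(cfg.volume_shape))
    encoders = {
        "smri": Sequential([Flatten(), Dense(n_vox, cfg.latent_dim, rng)]),
        "fmri": Sequential([Flatten(), Dense(cfg.n_fnc_features, cfg.latent_dim, rng)]),
        "snp": Sequential([Flatten(), Dense(cfg.n_snps, cfg.latent_dim, rng)]),
    }
    if hidden:
        head = Sequential(
            [Dense(3 * cfg.latent_dim, 8, rng), ReLU(), Dense(8, 2, rng)]
        )
    else:
        head = Sequential([Dense(3 * cfg.latent_dim, 2, rng)])
    return FusionModel(encoders, head, cfg)


def _subject(cfg, rng, label="AD"):
    return ModalityInputs(
        subject_id="s0",
        class_label=label,
        volume=rng.normal(size=cfg.volume_shape),
        fnc=rng.uniform(-1, 1, size=cfg.n_fnc_features),
        snp=rng.integers(0, 3, size=cfg.n_snps).astype(float),
    )


SMALL = dict(latent_dim=4, volume_shape=(3, 3, 3), n_components=5, n_snps=10, ig_steps=8)


class TestIntegratedGradients:
    def test_input_equal_baseline_gives_zero(self):
        cfg = RunConfig(**SMALL)
        model = _linear_fusion_model(cfg)
        igcfg = IGConfig(n_steps=8, snp_baseline=np.zeros(cfg.n_snps))
        x = ModalityInputs(
            "s0", "CN",
            volume=np.zeros(cfg.volume_shape),
            fnc=np.zeros(cfg.n_fnc_features),
            snp=np.zeros(cfg.n_snps),
        )
        att = integrated_gradients(model, x, igcfg)
        assert np.all(att.smri == 0) and np.all(att.fmri == 0) and np.all(att.snp == 0)

    def test_linear_model_recovers_w_times_x_exactly(self):
        # for F(x) = w.x + b with zero baselines, IG_i = w_i x_i at any
        # number of path steps (the gradient is constant along the path)
        cfg = RunConfig(**SMALL)
        rng = np.random.default_rng(1)
        model = _linear_fusion_model(cfg, rng)
        igcfg = IGConfig(n_steps=4, snp_baseline=np.zeros(cfg.n_snps))
        x = _subject(cfg, rng)
        att = integrated_gradients(model, x, igcfg)
        t = att.predicted_class
        # effective linear weights per channel
        w_head = model.head.layers[0].w.value[:, t]
        d = cfg.latent_dim
        for mod, xin, got in (
            ("smri", x.volume.ravel(), att.smri.ravel()),
            ("fmri", x.fnc, att.fmri),
            ("snp", x.snp, att.snp),
        ):
            k = ["smri", "fmri", "snp"].index(mod)
            w_enc = model.encoders[mod].layers[1].w.value
            w_eff = w_enc @ w_head[k * d : (k + 1) * d]
            np.testing.assert_allclose(got, w_eff * xin, rtol=1e-9, atol=1e-12)
        assert abs(att.completeness_residual) < 1e-9 * max(1.0, abs(att.delta_f))

    def test_completeness_on_nonlinear_mlp(self):
        # relative completeness is meaningful only when F(x) - F(x') does
        # not nearly cancel; the fixed toy draws here have |delta F| >~ 0.7
        cfg = RunConfig(**SMALL)
        rng = np.random.default_rng(2)
        model = _linear_fusion_model(cfg, rng, hidden=True)
        igcfg = make_ig_config(cfg.n_snps, seed=5, n_steps=128)
        x = _subject(cfg, rng)
        att = integrated_gradients(model, x, igcfg)
        assert abs(att.delta_f) > 0.5
        assert abs(att.completeness_residual) < 0.01 * abs(att.delta_f)

    def test_residual_halves_as_steps_double(self):
        cfg = RunConfig(**SMALL)
        rng = np.random.default_rng(5)
        model = _linear_fusion_model(cfg, rng, hidden=True)
        x = _subject(cfg, rng)
        base = np.random.default_rng(55).standard_normal(cfg.n_snps)
        res = {}
        for m in (8, 16, 32, 64, 128, 256, 512):
            att = integrated_gradients(model, x, IGConfig(n_steps=m, snp_baseline=base))
            res[m] = abs(att.completeness_residual)
        for m in (8, 16, 32, 64, 128, 256):
            assert res[2 * m] <= 0.6 * res[m]  # ~1/m decay of the Riemann sum
        assert res[512] < res[8] / 32

    def test_implementation_invariance_on_identical_models(self):
        cfg = RunConfig(**SMALL)
        rng = np.random.default_rng(4)
        m1 = _linear_fusion_model(cfg, np.random.default_rng(11), hidden=True)
        m2 = _linear_fusion_model(cfg, np.random.default_rng(11), hidden=True)
        x = _subject(cfg, rng)
        igcfg = make_ig_config(cfg.n_snps, seed=6, n_steps=16)
        a1 = integrated_gradients(m1, x, igcfg)
        a2 = integrated_gradients(m2, x, igcfg)
        np.testing.assert_array_equal(a1.smri, a2.smri)
        np.testing.assert_array_equal(a1.snp, a2.snp)

    def test_missing_channel_rejected(self):
        cfg = RunConfig(**SMALL)
        model = _linear_fusion_model(cfg)
        igcfg = make_ig_config(cfg.n_snps, seed=0)
        x = ModalityInputs("s0", "CN", volume=np.zeros(cfg.volume_shape))
        with pytest.raises(Exception, match="three channels"):
            integrated_gradients(model, x, igcfg)


class TestThresholding:
    def test_98th_percentile_of_1000_distinct_keeps_20(self):
        vals = np.random.default_rng(0).permutation(1000).astype(float) + 1.0
        idx, kept = threshold_attributions(vals, 98.0, mode="absolute")
        assert len(idx) == 20
        assert set(kept) == set(np.sort(vals)[-20:])

    def test_all_zero_map_keeps_nothing(self):
        idx, _ = threshold_attributions(np.zeros(100), 99.5)
        assert len(idx) == 0

    def test_positive_mode_on_all_negative_empty(self):
        vals = -np.abs(np.random.default_rng(1).normal(size=50)) - 0.1
        idx, _ = threshold_attributions(vals, 65.0, mode="positive")
        assert len(idx) == 0

    @settings(derandomize=True, max_examples=20)
    @given(
        seed=st.integers(0, 1000),
        pct=st.sampled_from([65.0, 98.0, 99.5]),
        n=st.integers(10, 400),
    )
    def test_counting_matches_sorting_oracle(self, seed, pct, n):
        vals = np.random.default_rng(seed).normal(size=n)
        idx, kept = threshold_attributions(vals, pct, mode="absolute")
        cut = np.percentile(np.abs(vals), pct)
        oracle = {i for i, v in enumerate(vals) if abs(v) > cut}
        assert set(idx) == oracle

    def test_threshold_map_zeroes_nonsurvivors(self):
        vals = np.array([[0.1, -5.0], [0.2, 3.0]])
        out = threshold_map(vals, 50.0)
        assert out.shape == vals.shape
        np.testing.assert_array_equal(out, [[0.0, -5.0], [0.0, 3.0]])


class TestRegionAggregation:
    def _atlas(self):
        atlas = np.zeros((4, 4, 1), dtype=int)
        atlas[:2] = 1
        atlas[2:] = 2
        return atlas

    def test_constant_region_mean(self):
        atlas = self._atlas()
        m = np.where(atlas == 1, 0.7, 0.0)
        table, retained = aggregate_regions([m], atlas, retention_fraction=0.99)
        assert table.loc[0, 1] == pytest.approx(0.7)
        assert retained == [1]

    def test_retention_boundary_99_of_100(self):
        atlas = self._atlas()
        surviving = np.where(atlas == 1, 1.0, 0.0)
        empty = np.zeros_like(surviving)
        maps_99 = [surviving] * 99 + [empty]
        _, retained = aggregate_regions(maps_99, atlas, retention_fraction=0.99)
        assert 1 in retained
        maps_98 = [surviving] * 98 + [empty] * 2
        _, retained = aggregate_regions(maps_98, atlas, retention_fraction=0.99)
        assert 1 not in retained

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            aggregate_regions([np.zeros((2, 2, 2))], self._atlas())


class TestConnectogram:
    def _partition(self):
        return NetworkPartition({0: "SM", 1: "SM", 2: "CB", 3: "VI", 4: "VI"})

    def test_intra_and_inter_flags(self):
        # n=5 components, 10 connections; edge (0,1) intra-SM, (1,2) SM-CB
        vec = np.zeros(10)
        vec[0] = 5.0   # (0,1)
        vec[4] = -4.0  # (1,2)
        edges, _ = build_connectogram(vec, self._partition(), percentile=75.0)
        kinds = {(r.component_i, r.component_j): r.kind for r in edges.itertuples()}
        assert kinds[(0, 1)] == "intra"
        assert kinds[(1, 2)] == "inter"

    def test_network_percentage_counting(self):
        rng = np.random.default_rng(0)
        vec = rng.normal(size=10) * 0.01
        vec[0] = 3.0  # (0,1) SM-SM
        vec[1] = 2.5  # (0,2) SM-CB
        vec[9] = -2.8  # (3,4) VI-VI
        edges, summary = build_connectogram(vec, self._partition(), percentile=70.0)
        assert len(edges) == 3
        assert summary["SM"] == pytest.approx(100 * 2 / 3)
        assert summary["VI"] == pytest.approx(100 * 1 / 3)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="n\\(n-1\\)/2"):
            build_connectogram(np.zeros(11), self._partition())


class TestSelectSnps:
    def test_five_element_enumeration(self):
        vals = np.array([-5.0, -1.0, 0.5, 2.0, 3.0])
        # |v| sorted: [0.5, 1, 2, 3, 5]; 65th percentile = 2.6 by linear
        # interpolation; positive survivors strictly above: only 3.0
        cut = np.percentile(np.abs(vals), 65.0)
        oracle = [i for i in np.argsort(-vals) if vals[i] > 0 and abs(vals[i]) > cut]
        assert select_snps(vals, 65.0) == oracle == [4]

    def test_all_negative_empty(self):
        assert select_snps(np.array([-1.0, -2.0, -0.5]), 65.0) == []

    def test_large_outlier_ranked_first(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30) * 0.1
        vals[17] = 10.0
        assert select_snps(vals, 65.0)[0] == 17

    def test_sorted_by_descending_attribution(self):
        vals = np.array([0.0, 3.0, 1.0, 5.0, 2.0, -9.0])
        got = select_snps(vals, 30.0)
        assert got == sorted(got, key=lambda i: -vals[i])


def exact_rank_sum_p(x, y):
    """Exhaustive two-sided rank-sum p-value (no ties assumed)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    w_obs = sum(ranks[v] for v in x)
    mu = n * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        w = sum(r + 1 for r in comb)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestGroupStats:
    def test_rank_sum_toy_example(self):
        # {1,2,3} vs {4,5,6}: 2 of C(6,3)=20 assignments are as extreme
        p = rank_sum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n,m,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (8, 7, 3)])
    def test_rank_sum_matches_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, n + m + 1))  # distinct values
        x, y = pooled[:n], pooled[n:]
        assert rank_sum_test(x, y) == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.008, 6) == pytest.approx(0.048)
        assert bonferroni(0.5, 6) == 1.0

    def test_identical_groups_kw_null(self):
        labels = np.repeat(["CN", "AD", "MCInc", "MCIc"], 5)
        table = pd.DataFrame({"f0": np.tile(np.arange(5.0), 4)})
        report = group_stats(table, labels)
        h, p = report.kruskal["f0"]
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99
        assert "f0" not in report.pairwise  # gate closed, no pairwise stage

    def test_strong_difference_triggers_all_six_contrasts(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(["CN", "AD", "MCInc", "MCIc"], 10)
        vals = np.concatenate([
            rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10),
            rng.normal(10, 0.1, 10), rng.normal(15, 0.1, 10),
        ])
        report = group_stats(pd.DataFrame({"f0": vals}), labels)
        assert set(report.pairwise["f0"]) == {
            "AD-CN", "AD-MCIc", "AD-MCInc", "CN-MCIc", "CN-MCInc", "MCIc-MCInc"
        }
        for raw, adj in report.pairwise["f0"].values():
            assert adj == pytest.approx(min(1.0, raw * 6))

    def test_small_group_skipped_with_warning(self):
        labels = np.array(["CN"] * 5 + ["AD"] * 5 + ["MCInc"] * 5 + ["MCIc"] * 2)
        table = pd.DataFrame({"f0": np.arange(17.0)})
        report = group_stats(table, labels)
        assert report.skipped == ["f0"]

    def test_report_serializable(self):
        import json

        rng = np.random.default_rng(1)
        labels = np.repeat(["CN", "AD", "MCInc", "MCIc"], 8)
        table = pd.DataFrame({
            "a": rng.normal(size=32),
            "b": np.concatenate([rng.normal(i, 0.1, 8) for i in range(4)]),
        })
        report = group_stats(table, labels)
        payload = json.dumps(report.to_dict())
        assert "kruskal" in json.loads(payload)
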