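"""Generator moments, variance inflation, attenuation identity, truth."""

import numpy as np
import pytest

from roikst.exceptions import ConfigurationError
from roikst.synthetic_data import (SimulationConfig, calibrate_effect_sizes,
                                   null_config, simulate_dataset,
                                   simulate_genotypes, simulate_methylation,
                                   simulate_phenotype)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize("kwargs", [
        {"heritabilities": (0.05, 0.07, 0.04, 0.03, 0.01)},  # not decreasing
        {"heritabilities": (0.5, 0.3, 0.1, 0.08, 0.05)},     # sums to >= 1
        {"maf": 0.01},
        {"variance_inflation": 1.0},
        {"n": 5},
        {"residual_sd": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_null_config_allows_zero_effects(self):
        cfg = null_config()
        assert all(h == 0 for h in cfg.heritabilities)


class TestGenotypes:
    def test_hardy_weinberg_moments(self):
        cfg = SimulationConfig(n=10_000, maf=0.5)
        g = simulate_genotypes(cfg, np.random.default_rng(1)).values
        se = np.sqrt(2 * 0.5 * 0.5 / cfg.n)
        assert abs(g[:, 0].mean() - 1.0) < 3 * se

    def test_rare_homozygote_frequency(self):
        cfg = SimulationConfig(n=10_000, maf=0.05)
        g = simulate_genotypes(cfg, np.random.default_rng(2)).values
        freq2 = np.mean(g[:, 0] == 2)
        se = np.sqrt(0.0025 * 0.9975 / cfg.n)
        assert abs(freq2 - 0.0025) < 3 * se

    def test_seeded_determinism(self):
        cfg = SimulationConfig()
        a = simulate_genotypes(cfg, np.random.default_rng(3)).values
        b = simulate_genotypes(cfg, np.random.default_rng(3)).values
        np.testing.assert_array_equal(a, b)


class TestMethylation:
    def test_values_in_unit_interval(self):
        cfg = SimulationConfig(n=500)
        pre, post = simulate_methylation(cfg, np.random.default_rng(4))
        for mat in (pre, post):
            assert mat.values.min() >= 0.0
            assert mat.values.max() <= 1.0

    def test_anchor_cpgs_have_inflated_treatment_variance(self):
        cfg = SimulationConfig(n=10_000)
        pre, post = simulate_methylation(cfg, np.random.default_rng(5))
        delta = post.values - pre.values
        anchors = [i for i, mid in enumerate(post.marker_ids)
                   if mid == cfg.anchor_cpg_id(
                       int(mid.split("_")[0][3:]) - 1)]
        others = [i for i in range(len(post.marker_ids))
                  if i not in anchors]
        var_anchor = delta[:, anchors].var(axis=0).mean()
        var_other = delta[:, others].var(axis=0).mean()
        assert var_anchor > 2.0 * var_other  # inflation factor 3 on logit sd


class TestPhenotype:
    def test_full_methylation_annihilates_snp_effect(self):
        """At beta value 1 everywhere the causal term is exactly zero."""
        cfg = SimulationConfig(n=400)
        rng = np.random.default_rng(6)
        g = simulate_genotypes(cfg, rng)
        pre, post = simulate_methylation(cfg, rng)
        ones = type(post)(sample_ids=post.sample_ids,
                          marker_ids=post.marker_ids,
                          values=np.ones_like(post.values),
                          marker_kind="methylation")
        rng_a = np.random.default_rng(7)
        rng_b = np.random.default_rng(7)
        with_effect = simulate_phenotype(cfg, g, ones, rng_a)
        null_cfg = null_config(n=400)
        no_effect = simulate_phenotype(null_cfg, g, ones, rng_b)
        np.testing.assert_allclose(with_effect.response,
                                   no_effect.response, atol=1e-12)

    def test_unmethylated_maximizes_association(self):
        """Effect at m = 0 exceeds the attenuated effect in correlation."""
        cfg = SimulationConfig(n=2000)
        rng = np.random.default_rng(8)
        g = simulate_genotypes(cfg, rng)
        _, post = simulate_methylation(cfg, rng)
        zeros = type(post)(sample_ids=post.sample_ids,
                           marker_ids=post.marker_ids,
                           values=np.zeros_like(post.values),
                           marker_kind="methylation")
        y_max = simulate_phenotype(cfg, g, zeros, np.random.default_rng(9))
        y_att = simulate_phenotype(cfg, g, post, np.random.default_rng(9))
        gv = g.values[:, 0]
        assert abs(np.corrcoef(gv, y_max.response)[0, 1]) > \
            abs(np.corrcoef(gv, y_att.response)[0, 1])

    def test_attenuation_identity(self):
        """Regressing y on (g, m, g*m) recovers (beta, 0, -beta)."""
        cfg = SimulationConfig(n=4000)
        rng = np.random.default_rng(10)
        g = simulate_genotypes(cfg, rng)
        _, post = simulate_methylation(cfg, rng)
        table = simulate_phenotype(cfg, g, post, rng)
        beta = calibrate_effect_sizes(cfg)[0]
        gv = g.values[:, 0]
        mv = post.restrict_markers([cfg.anchor_cpg_id(0)]).values[:, 0]
        X = np.column_stack([np.ones(cfg.n),
                             table.covariates.to_numpy(),
                             gv, mv, gv * mv])
        coef, *_ = np.linalg.lstsq(X, table.response, rcond=None)
        resid = table.response - X @ coef
        sigma = np.sqrt(resid @ resid / (cfg.n - X.shape[1]))
        se_scale = sigma / np.sqrt(cfg.n)
        assert abs(coef[3] - beta) < 10 * se_scale      # g term ~ beta
        assert abs(coef[5] + beta) < 20 * se_scale      # g*m term ~ -beta


class TestDataset:
    def test_layout_and_truth(self, dataset):
        assert len(dataset.regions) == 10
        causal = [t for t in dataset.truth if t.causal]
        assert len(causal) == 5
        effects = [t.effect_size for t in causal]
        assert all(a > b for a, b in zip(effects, effects[1:]))
        # each region on its own chromosome, anchor centered
        for t in dataset.truth:
            region = dataset.regions[t.region]
            assert region.anchor == t.anchor_cpg
            chroms = {dataset.annotation.lookup(m)[0]
                      for m in region.members}
            assert len(chroms) == 1

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n=40)
        a = simulate_dataset(cfg, seed=5)
        b = simulate_dataset(cfg, seed=5)
        np.testing.assert_array_equal(a.samples.response, b.samples.response)
        np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n=40)
        a = simulate_dataset(cfg, seed=5)
        b = simulate_dataset(cfg, seed=6)
        assert not np.array_equal(a.samples.response, b.samples.response)

    def test_alignment_across_components(self, dataset):
        assert dataset.samples.sample_ids == dataset.genotypes.sample_ids
        assert dataset.samples.sample_ids == \
            dataset.methylation_post.sample_ids
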