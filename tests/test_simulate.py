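"""Synthetic community generator: conservation, closure, determinism,
and the distributional contracts each downstream stage relies on."""

import numpy as np
import pytest
from scipy import stats

from phylloload import (
    GeneratorConfig,
    draw_compositions,
    draw_loads,
    generate,
    simulate_amplicon,
    simulate_metagenome,
)
from phylloload.simulate import ConfigError


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(bloom_prob=1.5)
        with pytest.raises(ConfigError):
            GeneratorConfig(load_bounds=(0.5, 0.1))
        with pytest.raises(ConfigError):
            GeneratorConfig(n_taxa_meta=1)

    def test_taxon_sets_partition(self):
        cfg = GeneratorConfig(n_taxa_meta=30, n_taxa_amp=25, shared_fraction=0.8)
        sets = cfg.taxon_sets()
        assert (sets == "shared").sum() == 20
        assert (sets == "meta_only").sum() == 10
        assert (sets == "amp_only").sum() == 5
        assert len(cfg.meta_labels()) == 30
        assert len(cfg.amp_labels()) == 25
        # shared families are the most abundant ones (head of the rank profile)
        assert sets.iloc[0] == "shared" and sets.iloc[1] == "shared"


class TestDrawLoads:
    def test_truncation_forces_range(self):
        cfg = GeneratorConfig(n_samples=200, load_bounds=(0.3, 0.3001))
        loads = draw_loads(cfg, np.random.default_rng(0))
        assert ((loads >= 0.3) & (loads <= 0.3001)).all()

    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_samples=50)
        a = draw_loads(cfg, np.random.default_rng(42))
        b = draw_loads(cfg, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_zero_variance_limit(self):
        cfg = GeneratorConfig(n_samples=10, load_log_sd=0.0)
        loads = draw_loads(cfg, np.random.default_rng(0))
        assert np.allclose(loads, np.exp(cfg.load_log_mean))


class TestDrawCompositions:
    def test_closure(self):
        cfg = GeneratorConfig(n_samples=30)
        comp, _ = draw_compositions(cfg, np.random.default_rng(1))
        assert comp.shape == (30, cfg.n_universe)
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)

    def test_bloom_prob_zero_means_no_blooms(self):
        cfg = GeneratorConfig(n_samples=50, bloom_prob=0.0)
        _, bloom = draw_compositions(cfg, np.random.default_rng(2))
        assert not bloom.any()

    def test_bloom_factor_one_is_identity(self):
        cfg1 = GeneratorConfig(n_samples=50, bloom_prob=0.5, bloom_factor=1.0)
        cfg2 = GeneratorConfig(n_samples=50, bloom_prob=0.5, bloom_factor=1.0)
        c1, _ = draw_compositions(cfg1, np.random.default_rng(3))
        c2, _ = draw_compositions(cfg2, np.random.default_rng(3))
        assert np.array_equal(c1, c2)

    def test_blooms_inflate_designated_taxon(self):
        cfg = GeneratorConfig(n_samples=400, bloom_prob=0.3, taxon_noise_sd=0.0)
        comp, bloom = draw_compositions(cfg, np.random.default_rng(4))
        assert 0 < bloom.sum() < 400
        assert comp[bloom, 0].mean() > comp[~bloom, 0].mean()


class TestSimulateMetagenome:
    def test_read_conservation_exact(self, desk_config):
        rng = np.random.default_rng(5)
        loads = draw_loads(desk_config, rng)
        comp, _ = draw_compositions(desk_config, rng)
        table, plant, unclassified = simulate_metagenome(loads, comp, desk_config, rng)
        classified = table.values.sum(axis=0)
        assert (plant + classified + unclassified == desk_config.total_depth).all()

    def test_fully_classifiable_leaves_nothing_unclassified(self):
        cfg = GeneratorConfig(n_samples=10, total_depth=50_000,
                              classifiable_fraction=1.0)
        rng = np.random.default_rng(6)
        loads = draw_loads(cfg, rng)
        comp, _ = draw_compositions(cfg, rng)
        _, _, unclassified = simulate_metagenome(loads, comp, cfg, rng)
        assert (unclassified == 0).all()

    def test_classified_to_plant_ratio_recovers_load(self):
        # law of large numbers at a fixed load: classified/plant -> f*L
        cfg = GeneratorConfig(n_samples=1000, total_depth=100_000,
                              load_log_mean=np.log(0.25), load_log_sd=0.0)
        rng = np.random.default_rng(7)
        loads = draw_loads(cfg, rng)
        comp, _ = draw_compositions(cfg, rng)
        table, plant, unclassified = simulate_metagenome(loads, comp, cfg, rng)
        classified = table.values.sum(axis=0)
        ratio = (classified + unclassified).mean() / plant.mean()
        assert ratio == pytest.approx(0.25, rel=0.02)
        classified_ratio = classified.mean() / plant.mean()
        assert classified_ratio == pytest.approx(
            0.25 * cfg.classifiable_fraction, rel=0.03
        )


class TestSimulateAmplicon:
    def test_columns_close_to_amplicon_depth(self, desk_config):
        rng = np.random.default_rng(8)
        comp, _ = draw_compositions(desk_config, rng)
        table, _ = simulate_amplicon(comp, desk_config, rng)
        assert (table.values.sum(axis=0) == desk_config.amplicon_depth).all()

    def test_unbiased_full_overlap_matches_composition(self):
        cfg = GeneratorConfig(
            n_samples=300, n_taxa_meta=10, n_taxa_amp=10, shared_fraction=1.0,
            primer_bias_sd=0.0, amplicon_depth=20_000, taxon_noise_sd=0.0,
            bloom_prob=0.0,
        )
        rng = np.random.default_rng(9)
        comp, _ = draw_compositions(cfg, rng)
        table, bias = simulate_amplicon(comp, cfg, rng)
        assert np.allclose(bias, 1.0)
        observed = table.values / cfg.amplicon_depth
        assert np.allclose(observed.mean(axis=1), comp.mean(axis=0), atol=5e-3)

    def test_counts_carry_no_load_information(self):
        """Identical compositions at loads 0.01 vs 0.7 give amplicon counts
        identical in law (KS test on a dominant taxon over replicates)."""
        cfg = GeneratorConfig(n_samples=500, amplicon_depth=5_000,
                              taxon_noise_sd=0.0, bloom_prob=0.0)
        rng = np.random.default_rng(10)
        comp = np.tile(cfg.base_profile(), (cfg.n_samples, 1))
        table_lo, bias = simulate_amplicon(comp, cfg, rng, primer_bias=np.ones(25))
        table_hi, _ = simulate_amplicon(comp, cfg, rng, primer_bias=np.ones(25))
        # loads never enter simulate_amplicon; the two calls differ only by rng
        lo = table_lo.values[0]
        hi = table_hi.values[0]
        assert stats.ks_2samp(lo, hi).pvalue > 0.01


class TestGenerate:
    def test_bit_reproducible(self, desk_config):
        a = generate(desk_config, seed=3)
        b = generate(desk_config, seed=3)
        assert a.meta_table.data.equals(b.meta_table.data)
        assert a.amp_table.data.equals(b.amp_table.data)
        assert a.metadata.data.equals(b.metadata.data)
        assert a.truth.true_load.equals(b.truth.true_load)

    def test_distinct_seeds_distinct_output(self, desk_config):
        a = generate(desk_config, seed=3)
        b = generate(desk_config, seed=4)
        assert not a.meta_table.data.equals(b.meta_table.data)

    def test_single_sample_dataset_valid(self):
        cfg = GeneratorConfig(n_samples=1, total_depth=10_000, amplicon_depth=500)
        ds = generate(cfg, seed=0)
        assert ds.meta_table.shape == (30, 1)
        assert ds.amp_table.shape == (25, 1)

    def test_truth_invariants(self, desk_dataset):
        t = desk_dataset.truth
        lo, hi = desk_dataset.config.load_bounds
        assert ((t.true_load >= lo) & (t.true_load <= hi)).all()
        assert np.allclose(t.base_composition.sum(axis=0), 1.0, atol=1e-9)
        assert (t.primer_bias > 0).all()

    def test_estimated_load_tracks_truth(self, desk_dataset):
        classified = desk_dataset.meta_table.values.sum(axis=0)
        plant = desk_dataset.metadata.plant_reads.to_numpy()
        r = np.corrcoef(classified / plant, desk_dataset.truth.true_load)[0, 1]
        assert r >= 0.95

    def test_dominant_shared_taxa_positively_correlated_in_truth(self, default_dataset):
        """Load variation drives every pair of dominant shared families to
        positive true-abundance correlation (the absolute-scale structure
        that closure later destroys)."""
        cfg = default_dataset.config
        profile = cfg.base_profile()
        dominant = [lab for lab, m, s in zip(
            cfg.family_labels(), profile, cfg.taxon_sets()
        ) if m >= 0.01 and s == "shared"]
        assert len(dominant) >= 4
        ta = default_dataset.truth.true_abundance.loc[dominant].to_numpy()
        cm = np.corrcoef(ta)
        off = cm[np.triu_indices(len(dominant), 1)]
        assert (off > 0).all()
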