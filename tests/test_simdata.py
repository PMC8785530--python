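"""Synthetic-data generator: LD mechanism, planted effects, phenotype model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import lactoqtl as lq
from lactoqtl.simdata import (
    _gamete,
    class_effects_from_means,
    draw_record_counts,
    simulate_yield_deviations,
)


def _tiny_config(**kw):
    defaults = dict(n_animals=200, n_structure_snps=20, n_dense_variants=60,
                    n_chromosomes=2, chrom_length_bp=20_000_000, seed=1)
    defaults.update(kw)
    return lq.PopulationConfig(**defaults)


class TestHaplotypePools:
    def test_no_recombination_gametes_are_exact_founder_copies(self):
        cfg = _tiny_config(recombination_rate=0.0, seed=3)
        pools = lq.simulate_haplotype_pools(cfg)
        chrom = pools.variants["chrom"].to_numpy()
        pos = pools.variants["pos"].to_numpy()
        slices = []
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            slices.append((idx[0], idx[-1] + 1, pos[idx]))
        rng = np.random.default_rng(0)
        for _ in range(10):
            hap = _gamete(pools.founders_a, slices, 0.0, rng)
            # each chromosome matches one founder exactly
            for start, stop, _p in slices:
                matches = (pools.founders_a[:, start:stop] == hap[start:stop]).all(axis=1)
                assert matches.any()

    def test_zero_divergence_pool_frequencies_match_binomial_null(self):
        cfg = _tiny_config(n_structure_snps=100, n_dense_variants=900,
                           divergence=0.0, seed=5)
        pools = lq.simulate_haplotype_pools(cfg)
        fa = pools.founders_a.mean(axis=0)
        fb = pools.founders_b.mean(axis=0)
        observed = np.mean(np.abs(fa - fb))
        # binomial-resampling oracle at the common target frequencies
        rng = np.random.default_rng(99)
        K = cfg.n_founders
        stats = [
            np.mean(np.abs(rng.binomial(K, pools.freq_a) / K
                           - rng.binomial(K, pools.freq_b) / K))
            for _ in range(200)
        ]
        mu, sd = np.mean(stats), np.std(stats)
        assert abs(observed - mu) < 3 * sd + 1e-12

    def test_divergence_target_realized_within_resampling_error(self):
        cfg = _tiny_config(n_structure_snps=200, n_dense_variants=1800,
                           divergence=0.1, seed=7)
        pools = lq.simulate_haplotype_pools(cfg)
        # the target mean absolute pool difference is the divergence parameter
        target_diff = np.mean(np.abs(pools.freq_a - pools.freq_b))
        assert abs(target_diff - 0.1) < 0.012  # clipping erodes a little
        fa = pools.founders_a.mean(axis=0)
        fb = pools.founders_b.mean(axis=0)
        observed = np.mean(np.abs(fa - fb))
        rng = np.random.default_rng(11)
        K = cfg.n_founders
        stats = [
            np.mean(np.abs(rng.binomial(K, pools.freq_a) / K
                           - rng.binomial(K, pools.freq_b) / K))
            for _ in range(200)
        ]
        assert abs(observed - np.mean(stats)) < 3 * np.std(stats)

    def test_too_many_variants_rejected(self):
        with pytest.raises(ValueError, match="positions available"):
            lq.simulate_haplotype_pools(
                _tiny_config(n_structure_snps=10_000_000, n_dense_variants=10_000_001)
            )


class TestCrossbredGenotypes:
    def test_pure_breed_mix_gives_unit_breed_fractions(self):
        cfg = _tiny_config(breed_mix=(1.0, 0.0, 0.0), seed=2)
        pools = lq.simulate_haplotype_pools(cfg)
        _, fracs = lq.simulate_crossbred_genotypes(pools, cfg)
        assert np.all(fracs[:, 0] == 1.0)
        assert np.all(fracs[:, 1] == 0.0)

    def test_genotype_count_and_maf_bounds(self):
        cfg = _tiny_config(seed=4)
        pools = lq.simulate_haplotype_pools(cfg)
        G, _ = lq.simulate_crossbred_genotypes(pools, cfg)
        hom_alt = (G.dosage == 2).sum(axis=0)
        assert np.all((hom_alt >= 0) & (hom_alt <= cfg.n_animals))
        maf = G.maf()
        assert np.all((maf >= 0.0) & (maf <= 0.5))

    def test_planted_variant_maf_within_binomial_error(self):
        cfg = _tiny_config(n_animals=10_000, n_structure_snps=10,
                           n_dense_variants=40, seed=6)
        pools = lq.simulate_haplotype_pools(cfg)
        pos = int(pools.variants.query("chrom == 1")["pos"].iloc[5])
        spec = lq.QTLSpec(chrom=1, pos=pos, maf_target=0.03, a_true=-1.0, d_true=1.0)
        G, _ = lq.simulate_crossbred_genotypes(pools, cfg, qtl_specs=[spec])
        j = np.flatnonzero((G.variants["chrom"] == 1) & (G.variants["pos"] == pos))[0]
        se = np.sqrt(0.03 * 0.97 / (2 * cfg.n_animals))
        assert abs(G.maf()[j] - 0.03) < 3 * se

    def test_dr2_fractions_roughly_configured(self):
        cfg = _tiny_config(n_structure_snps=500, n_dense_variants=4500,
                           n_animals=50, frac_dr2_below_07=0.05,
                           frac_dr2_07_09=0.10, seed=8)
        pools = lq.simulate_haplotype_pools(cfg)
        G, _ = lq.simulate_crossbred_genotypes(pools, cfg)
        dr2 = G.dr2
        assert abs(np.mean(dr2 < 0.7) - 0.05) < 0.02
        assert abs(np.mean((dr2 >= 0.7) & (dr2 < 0.9)) - 0.10) < 0.02


class TestPlantQtl:
    @pytest.mark.parametrize(
        "a,d,expected",
        [(-5.0, 5.0, (5.0, 5.0, -5.0)),     # fully recessive, k = 1
         (-5.0, 0.0, (5.0, 0.0, -5.0))],    # perfectly additive, k = 0
    )
    def test_class_deviation_coding(self, small_study, a, d, expected):
        G = small_study.genotypes
        row = small_study.truth.iloc[0]
        spec = lq.QTLSpec(chrom=int(row["chrom"]), pos=int(row["pos"]),
                          maf_target=0.2, a_true=a, d_true=d)
        g, truth = lq.plant_qtl(G, [spec])
        j = int(row["variant_index"])
        x = G.dosage[:, j]
        for c, val in zip((0, 1, 2), expected):
            assert np.allclose(g[x == c], val)
        assert truth["k_true"].iloc[0] == pytest.approx(d / abs(a))

    def test_class_mean_arithmetic_recovers_planted_effects(self):
        # stop-gain style locus: het and hom-alt produce 1.44 and 11.21 kg less
        a, d = class_effects_from_means(0.0, -1.44, -11.21)
        assert a == pytest.approx(-5.605)
        assert d == pytest.approx(4.165)
        assert round(d / abs(a), 2) == 0.74

    def test_noise_free_class_means_match_spec_to_machine_precision(self, small_study):
        G = small_study.genotypes
        row = small_study.truth.iloc[0]
        spec = lq.QTLSpec(chrom=int(row["chrom"]), pos=int(row["pos"]),
                          maf_target=0.2, a_true=-5.605, d_true=4.165)
        g, truth = lq.plant_qtl(G, [spec])
        t = truth.iloc[0]
        a_hat, d_hat = class_effects_from_means(
            t["mean_hom_ref"], t["mean_het"], t["mean_hom_alt"])
        assert a_hat == pytest.approx(-5.605, abs=1e-12)
        assert d_hat == pytest.approx(4.165, abs=1e-12)

    def test_monomorphic_spec_warns_and_contributes_zero(self, small_study):
        G = small_study.genotypes
        mono = np.flatnonzero(G.maf() == 0.0)
        if len(mono) == 0:
            j = 3
            G = lq.GenotypeMatrix(G.animals, G.variants.copy(), G.dosage.copy())
            G.dosage[:, j] = 0
        else:
            j = mono[0]
        v = G.variants.iloc[j]
        spec = lq.QTLSpec(chrom=v["chrom"], pos=int(v["pos"]), maf_target=0.01,
                          a_true=-3.0, d_true=3.0)
        with pytest.warns(UserWarning, match="monomorphic"):
            g, _ = lq.plant_qtl(G, [spec])
        assert np.all(g == 0.0)

    def test_unknown_position_rejected(self, small_study):
        spec = lq.QTLSpec(chrom=1, pos=123, maf_target=0.1, a_true=1.0, d_true=0.0)
        with pytest.raises(ValueError, match="not in the variant map"):
            lq.plant_qtl(small_study.genotypes, [spec])


class TestYieldDeviations:
    def test_noise_free_limit_returns_genetic_values(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=300)
        X = rng.binomial(2, 0.4, size=(300, 50))
        phen, _ = simulate_yield_deviations(g, X, 0.0, 0.0, 0.0, 1, rng)
        assert np.array_equal(phen.y, g)

    def test_equal_weights_residual_variance_matches_chi_square_interval(self):
        rng = np.random.default_rng(1)
        n, w, var_e = 4000, 4, 2.0
        g = np.zeros(n)
        X = rng.binomial(2, 0.4, size=(n, 20))
        phen, comps = simulate_yield_deviations(
            g, X, 0.0, 0.0, var_e, np.full(n, w), rng)
        s2 = np.var(comps["ebar"], ddof=1)
        lo = var_e / w * chi2.ppf(0.0005, n - 1) / (n - 1)
        hi = var_e / w * chi2.ppf(0.9995, n - 1) / (n - 1)
        assert lo < s2 < hi

    def test_variance_fraction_targets_realized(self):
        # targets on the scale of the largest purebred heritability table entry
        cfg = lq.PopulationConfig(n_animals=3000, n_structure_snps=200,
                                  n_dense_variants=200, n_chromosomes=2,
                                  chrom_length_bp=30_000_000, seed=13)
        study = lq.simulate_study(cfg, [], h2=0.296, delta2=0.044, record_counts=1)
        c = study.components
        assert np.var(c["u_add"]) == pytest.approx(0.296, abs=1e-9)
        assert np.var(c["u_dom"]) == pytest.approx(0.044, abs=1e-9)
        total = np.var(study.phenotypes.y)
        parts = sum(np.var(c[k]) for k in ("g", "u_add", "u_dom", "ebar"))
        # cross-covariances are the only discrepancy; they are O(1/sqrt(n))
        assert abs(total - parts) < 0.08

    def test_zero_record_count_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match=">= 1"):
            simulate_yield_deviations(np.zeros(10), np.zeros((10, 2)), 0.0, 0.0,
                                      1.0, np.zeros(10, dtype=int), rng)

    def test_record_counts_shifted_poisson_minimum_one(self):
        rng = np.random.default_rng(3)
        w = draw_record_counts(5000, rng, ("poisson", 7.0))
        assert w.min() >= 1
        assert abs(w.mean() - 8.0) < 0.2


class TestDeterminism:
    def test_fixed_seed_reproduces_identical_outputs(self, tmp_path):
        cfg = _tiny_config(seed=21)
        out = []
        for run in range(2):
            study = lq.simulate_study(cfg, [], h2=0.25, delta2=0.04)
            gpath = tmp_path / f"g{run}.tsv"
            ppath = tmp_path / f"p{run}.tsv"
            from lactoqtl.io import write_dosage_tsv, write_phenotypes
            write_dosage_tsv(study.genotypes, gpath)
            write_phenotypes(study.phenotypes, ppath)
            out.append((gpath.read_bytes(), ppath.read_bytes()))
        assert out[0][0] == out[1][0]
        assert out[0][1] == out[1][1]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            lq.PopulationConfig(breed_mix=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="> 0"):
            lq.PopulationConfig(n_animals=0)
        with pytest.raises(ValueError, match="maf_target"):
            lq.QTLSpec(chrom=1, pos=10, maf_target=0.7, a_true=1.0, d_true=0.0)
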