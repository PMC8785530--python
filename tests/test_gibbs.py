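"""BayesC0 Gibbs sampler, Geweke diagnostic, segment plan and LOSO algebra."""

import numpy as np
import pandas as pd
import pytest

import lactoqtl as lq
from lactoqtl.gibbs import (
    BayesC0Sampler,
    LosoAdjuster,
    geweke_diagnostic,
    partition_segments,
)


def _mcse(chain, batches=20):
    """Batch-means Monte-Carlo standard error of a chain mean."""
    chain = np.asarray(chain)
    b = len(chain) // batches
    means = chain[: b * batches].reshape(batches, b).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(batches)


class TestBayesC0:
    def test_null_phenotype_yields_null_effects(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.4, size=(400, 40)).astype(float)
        y = np.full(400, 3.0) + rng.normal(0, 0.01, 400)
        est = BayesC0Sampler(n_retained=300, burn_in=100, thin=1, seed=2)
        est.fit(X, y)
        s = est.samples_
        z = np.abs(s.alpha.mean(axis=0)) / s.alpha.std(axis=0, ddof=1)
        assert np.mean(z < 3) > 0.9
        assert z.max() < 5

    def test_generative_variance_recovery(self):
        rng = np.random.default_rng(3)
        n, p = 1000, 300
        X = rng.binomial(2, 0.35, size=(n, p)).astype(float)
        het = (X == 1).astype(float)
        var_a, var_d, var_e = 0.002, 0.001, 0.5
        alpha = rng.normal(0, np.sqrt(var_a), p)
        delta = rng.normal(0, np.sqrt(var_d), p)
        y = X @ alpha + het @ delta + rng.normal(0, np.sqrt(var_e), n)
        est = BayesC0Sampler(n_retained=600, burn_in=300, thin=1, seed=4)
        est.fit(X, y)
        s = est.samples_
        for chain, truth in [(s.var_alpha, var_a), (s.var_delta, var_d),
                             (s.var_e, var_e)]:
            assert abs(chain.mean() - truth) < 3 * chain.std(ddof=1)

    def test_matches_ridge_solution_when_dominance_disabled(self):
        rng = np.random.default_rng(5)
        n, p = 400, 40
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        beta = rng.normal(0, 0.3, p)
        y = X @ beta + rng.normal(0, 1.0, n)
        est = BayesC0Sampler(n_retained=2000, burn_in=300, thin=1,
                             include_dominance=False, seed=6)
        est.fit(X, y)
        s = est.samples_
        lam = s.var_e.mean() / s.var_alpha.mean()
        Ma = X - X.mean(axis=0)
        ridge = np.linalg.solve(Ma.T @ Ma + lam * np.eye(p), Ma.T @ (y - y.mean()))
        post_mean = s.alpha.mean(axis=0)
        tol = 6 * np.array([_mcse(s.alpha[:, j]) for j in range(p)]) + 1e-3
        assert np.all(np.abs(post_mean - ridge) < tol)

    def test_zero_variance_column_pinned_to_zero(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.4, size=(200, 10)).astype(float)
        X[:, 4] = 2.0
        y = rng.normal(size=200)
        est = BayesC0Sampler(n_retained=100, burn_in=50, thin=1, seed=8).fit(X, y)
        assert np.all(est.samples_.alpha[:, 4] == 0.0)

    def test_nonfinite_phenotype_rejected(self):
        X = np.zeros((10, 2))
        y = np.zeros(10)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            BayesC0Sampler().fit(X, y)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.3, size=(150, 20)).astype(float)
        y = rng.normal(size=150)
        runs = [BayesC0Sampler(n_retained=80, burn_in=20, thin=1, seed=11).fit(X, y)
                for _ in range(2)]
        assert np.array_equal(runs[0].samples_.alpha, runs[1].samples_.alpha)
        assert np.array_equal(runs[0].samples_.var_e, runs[1].samples_.var_e)

    def test_column_order_exchangeability_of_fitted_values(self):
        # fitted phenotype adjustments should not depend on SNP ordering
        rng = np.random.default_rng(10)
        n, p = 300, 30
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        y = X @ rng.normal(0, 0.4, p) + rng.normal(0, 0.5, n)
        est1 = BayesC0Sampler(n_retained=1500, burn_in=300, thin=1, seed=12).fit(X, y)
        perm = rng.permutation(p)
        est2 = BayesC0Sampler(n_retained=1500, burn_in=300, thin=1, seed=13).fit(X[:, perm], y)
        fit1 = (est1.M_alpha_ @ est1.samples_.alpha.T).mean(axis=1)
        fit2 = (est2.M_alpha_ @ est2.samples_.alpha.T).mean(axis=1)
        assert np.corrcoef(fit1, fit2)[0, 1] > 0.98


class TestGeweke:
    def test_null_calibration(self):
        # nominal coverage of |z| < 2 under N(0,1) is 95.45%; allow 3
        # binomial SEs (~1.5% at 200 replicates) of sampling noise
        rng = np.random.default_rng(21)
        flags = [abs(geweke_diagnostic(rng.standard_normal(10_000))[0]) < 2
                 for _ in range(200)]
        nominal = 0.9545
        bound = nominal - 3 * np.sqrt(nominal * (1 - nominal) / 200)
        assert np.mean(flags) >= bound

    def test_linear_trend_flagged(self):
        z, _ = geweke_diagnostic(np.linspace(0, 1, 5000))
        assert abs(z) > 5

    def test_constant_chain_degenerate(self):
        z, degenerate = geweke_diagnostic(np.ones(500))
        assert z == 0.0
        assert degenerate

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            geweke_diagnostic(np.arange(10))


class TestSegmentPlan:
    def test_25mb_chromosome_tiles_into_three_segments(self):
        vm = pd.DataFrame({"chrom": [1, 1], "pos": [5, 25_000_000]})
        plan = partition_segments(vm, segment_bp=10_000_000)
        seg = plan.segments
        assert len(seg) == 3
        assert seg["end_bp"].tolist() == [10_000_000, 20_000_000, 25_000_000]

    def test_boundary_position_follows_zero_based_half_open_rule(self):
        vm = pd.DataFrame({"chrom": [1, 1, 1],
                           "pos": [1, 10_000_000, 10_000_001]})
        plan = partition_segments(vm, segment_bp=10_000_000)
        seg = plan.assign(vm["chrom"].to_numpy(), vm["pos"].to_numpy())
        # 1-based position p belongs to tile floor((p-1)/10Mb)
        assert seg.tolist() == [0, 0, 1]

    def test_every_variant_assigned_exactly_once(self):
        rng = np.random.default_rng(31)
        vm = pd.DataFrame({
            "chrom": np.repeat([1, 2, 3], 200),
            "pos": np.concatenate([np.sort(rng.choice(50_000_000, 200, replace=False)) + 1
                                   for _ in range(3)]),
        })
        plan = partition_segments(vm)
        seg = plan.assign(vm["chrom"].to_numpy(), vm["pos"].to_numpy())
        assert len(seg) == len(vm)
        assert set(seg).issubset(set(plan.seg_ids))

    def test_unknown_position_raises(self):
        vm = pd.DataFrame({"chrom": [1], "pos": [100]})
        plan = partition_segments(vm)
        with pytest.raises(KeyError):
            plan.assign(np.array([2]), np.array([100]))


@pytest.fixture(scope="module")
def fitted_loso():
    rng = np.random.default_rng(41)
    n, p = 400, 60
    pos = np.sort(rng.choice(np.arange(1, 40_000_000), p, replace=False))
    chrom = np.ones(p, dtype=int)
    X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
    y = X @ rng.normal(0, 0.2, p) + rng.normal(0, 0.8, n)
    est = BayesC0Sampler(n_retained=150, burn_in=100, thin=1, seed=42).fit(X, y)
    vm = pd.DataFrame({"chrom": chrom, "pos": pos})
    plan = partition_segments(vm)
    adj = LosoAdjuster.from_sampler(y, est, chrom, pos, plan)
    return adj, y, est


class TestLoso:
    def test_whole_genome_segment_leaves_only_mean_adjustment(self):
        rng = np.random.default_rng(43)
        n, p = 200, 20
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        y = rng.normal(size=n)
        est = BayesC0Sampler(n_retained=100, burn_in=50, thin=1, seed=44).fit(X, y)
        vm = pd.DataFrame({"chrom": np.ones(p, dtype=int),
                           "pos": np.arange(1, p + 1) * 1000})
        plan = partition_segments(vm, segment_bp=10**9)
        adj = LosoAdjuster.from_sampler(y, est, vm["chrom"].to_numpy(),
                                        vm["pos"].to_numpy(), plan)
        expected = y[:, None] - est.samples_.mu[None, :]
        assert np.allclose(adj.adjusted(0), expected, atol=1e-8)

    def test_addback_identity_matches_direct_sum(self, fitted_loso):
        adj, _, _ = fitted_loso
        for s in adj.plan.seg_ids:
            assert np.allclose(adj.adjusted(int(s)), adj.adjusted_direct(int(s)),
                               atol=1e-8)

    def test_addback_equals_segment_contribution_exactly(self, fitted_loso):
        adj, _, _ = fitted_loso
        for s in adj.plan.seg_ids:
            diff = adj.adjusted(int(s)) - adj.base_
            assert np.allclose(diff, adj.addback(int(s)), atol=1e-12)

    def test_unknown_segment_id_rejected(self, fitted_loso):
        adj, _, _ = fitted_loso
        with pytest.raises(KeyError):
            adj.adjusted(999)

    def test_loso_restores_signal_absorbed_by_full_adjustment(self):
        # a QTL fitted among the structure SNPs is shrunk out of the fully
        # adjusted residual; the LOSO add-back restores its effect
        rng = np.random.default_rng(45)
        n, p = 1500, 40
        pos = np.sort(rng.choice(np.arange(1, 40_000_000), p, replace=False))
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        j = 10
        a_true = 0.8
        y = a_true * X[:, j] + rng.normal(0, 1.0, n)
        est = BayesC0Sampler(n_retained=200, burn_in=150, thin=1, seed=46).fit(X, y)
        vm = pd.DataFrame({"chrom": np.ones(p, dtype=int), "pos": pos})
        plan = partition_segments(vm)
        adj = LosoAdjuster.from_sampler(y, est, vm["chrom"].to_numpy(),
                                        vm["pos"].to_numpy(), plan)
        seg_j = int(plan.assign(np.array([1]), np.array([pos[j]]))[0])
        x = X[:, j] - X[:, j].mean()
        sxx = float(x @ x)
        slope_loso = float(x @ adj.adjusted(seg_j).mean(axis=1)) / sxx
        slope_full = float(x @ adj.base_.mean(axis=1)) / sxx
        se = 1.0 / np.sqrt(sxx)
        assert abs(slope_loso - a_true) < 3 * se
        assert slope_full < slope_loso - 3 * se  # attenuated without add-back
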