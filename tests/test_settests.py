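"""Unit and oracle-equivalence tests for the four SNP-set association tests."""

import numpy as np
import pytest
from scipy import stats

from snpset import (
    TestConfig,
    center_kernel,
    kpca_test,
    linear_kernel,
    pca_components,
    pca_test,
    rbf_kernel,
    screen_snps,
    single_snp_tests,
    sir_eigen,
    sir_test,
    spca_test,
)


def _xy(ds):
    return ds.genotypes.astype(float), ds.phenotype.astype(float)


class TestPCAComponents:
    def test_dominant_eigenvalue_needs_one_component(self):
        rng = np.random.default_rng(0)
        # two orthogonal directions with variance ratio 9:1
        z = rng.standard_normal((500, 2)) * [3.0, 1.0]
        comp = pca_components(z, 0.8)
        assert comp.k == 1

    def test_equicorrelated_closed_form(self):
        # 10 exchangeable variables with common correlation r:
        # leading eigenvalue fraction (1 + 9r)/10
        rng = np.random.default_rng(1)
        r = np.sqrt(0.8)
        C = np.full((10, 10), r)
        np.fill_diagonal(C, 1.0)
        X = rng.multivariate_normal(np.zeros(10), C, size=4000)
        comp = pca_components(X, 0.8)
        lead = comp.eigenvalues[0] / comp.eigenvalues.sum()
        assert lead == pytest.approx((1 + 9 * r) / 10, abs=0.02)
        assert comp.k == 1

    def test_identity_covariance_needs_eight_of_ten(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20000, 10))
        comp = pca_components(X, 0.8)
        assert comp.k == 8

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 6))
        comp = pca_components(X, 1.0)
        assert np.allclose(comp.loadings.T @ comp.loadings, np.eye(comp.k), atol=1e-10)
        for j in range(comp.k):
            col = comp.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_components(np.ones((50, 3)), 0.8)


class TestPCATest:
    def test_composition_matches_direct_fit(self, fixed_dataset):
        """PCA test equals an independent Newton fit on explicit PC scores."""
        sm = pytest.importorskip("statsmodels.api")
        G, y = _xy(fixed_dataset)
        res = pca_test(G, y)
        comp = pca_components(G, 0.8)
        fit = sm.Logit(y, sm.add_constant(comp.scores)).fit(disp=0, method="newton")
        assert res.statistic == pytest.approx(2 * (fit.llf - fit.llnull), abs=1e-6)
        assert res.df == comp.k

    def test_permuted_phenotype_pvalues_uniform(self, null_dataset):
        G, y = _xy(null_dataset)
        rng = np.random.default_rng(8)
        pvals = [pca_test(G, rng.permutation(y)).p_value for _ in range(300)]
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_loadings_exposed_for_report(self, fixed_dataset):
        G, y = _xy(fixed_dataset)
        res = pca_test(G, y)
        assert res.component_loadings.shape == (10, res.n_components)


class TestScreening:
    def test_balanced_snp_scores_zero(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        g = np.tile(np.r_[np.ones(15), np.zeros(15)], 2)[:, None]
        scr = screen_snps(np.hstack([g, np.random.default_rng(0).integers(0, 3, (60, 1))]), y)
        assert scr.statistics[0] == pytest.approx(0.0, abs=1e-12)

    def test_causal_snp_ranks_first_on_average(self):
        from snpset import ScenarioSpec, simulate_case_control

        spec = ScenarioSpec("t", 10, (0.2,) * 10, 0.2, (3,), (1.5,), 500, 500)
        top = 0
        for seed in range(8):
            ds = simulate_case_control(spec, np.random.default_rng(seed))
            scr = screen_snps(*_xy(ds))
            top += scr.ranks[3] == 0
        assert top >= 5

    def test_ties_rank_stable_by_index(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        g = np.zeros((40, 3))
        g[:, 1] = np.r_[np.ones(20), np.zeros(20)]  # duplicated signal
        g[:, 2] = g[:, 1]
        scr = screen_snps(g, y)
        assert scr.statistics[1] == scr.statistics[2]
        assert scr.ranks[1] < scr.ranks[2]


class TestSPCA:
    def test_degenerate_grid_equals_single_pc_pca(self, fixed_dataset):
        """Grid {0} keeps all SNPs, so the statistic is the PC1 logistic LRT."""
        from snpset._glm import logistic_lrt

        G, y = _xy(fixed_dataset)
        config = TestConfig(screening_grid=(0.0,), n_permutations=100)
        res = spca_test(G, y, config, np.random.default_rng(0))
        comp = pca_components(G, 0.8)
        stat1, _, _, _ = logistic_lrt(y, comp.scores[:, 0])
        assert res.statistic == pytest.approx(stat1, abs=1e-6)

    def test_permutation_pvalue_floor(self, fixed_dataset):
        G, y = _xy(fixed_dataset)
        config = TestConfig(n_permutations=100, adaptive_permutations=False)
        res = spca_test(G, y, config, np.random.default_rng(1))
        assert res.p_value >= 1 / 101

    def test_null_pvalues_superuniform(self, null_dataset):
        # P(p <= alpha) <= alpha for permutation p-values under the null
        G, y = _xy(null_dataset)
        rng = np.random.default_rng(2)
        config = TestConfig(n_permutations=200)
        pvals = np.array(
            [
                spca_test(G, rng.permutation(y), config, rng).p_value
                for _ in range(60)
            ]
        )
        for alpha in (0.05, 0.1, 0.25):
            assert np.mean(pvals <= alpha) <= alpha + 2.5 * np.sqrt(
                alpha * (1 - alpha) / 60
            )

    def test_fixed_threshold_zero_equals_degenerate_grid(self, fixed_dataset):
        G, y = _xy(fixed_dataset)
        rng = np.random.default_rng(7)
        res_fixed = spca_test(
            G, y,
            TestConfig(fixed_screening_threshold=0.0, n_permutations=100),
            rng,
        )
        res_grid = spca_test(
            G, y, TestConfig(screening_grid=(0.0,), n_permutations=100),
            np.random.default_rng(7),
        )
        assert res_fixed.statistic == pytest.approx(res_grid.statistic, abs=1e-9)

    def test_selected_snps_reported(self, fixed_dataset):
        G, y = _xy(fixed_dataset)
        res = spca_test(G, y, TestConfig(n_permutations=100),
                        np.random.default_rng(3))
        assert res.n_components == 1
        assert len(res.selected_snps) >= 1
        assert set(res.selected_snps) <= set(range(10))


class TestKernels:
    def test_identical_rows_give_unit_kernel_entry(self):
        X = np.tile([1.0, 2.0, 0.0], (4, 1))
        K, sigma = rbf_kernel(X, 1.0)
        assert np.allclose(K, 1.0)

    def test_centered_kernel_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        K, _ = rbf_kernel(rng.integers(0, 3, (40, 5)), "auto")
        Kc = center_kernel(K)
        assert np.allclose(Kc.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Kc.sum(axis=1), 0.0, atol=1e-10)

    def test_infinite_bandwidth_limit_is_flat(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (30, 4))
        K, _ = rbf_kernel(X, 1e8)
        assert np.allclose(K, 1.0, atol=1e-10)
        assert np.allclose(center_kernel(K), 0.0, atol=1e-8)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rbf_kernel(np.zeros((5, 2)), 0.0)

    def test_matches_sklearn_rbf(self):
        sk = pytest.importorskip("sklearn.metrics.pairwise")
        rng = np.random.default_rng(2)
        X = rng.standard_normal((25, 3))
        K, sigma = rbf_kernel(X, 1.7)
        ref = sk.rbf_kernel(X, gamma=1 / (2 * 1.7**2))
        assert np.allclose(K, ref, atol=1e-12)


class TestKPCA:
    def test_linear_kernel_duality_with_pca(self, fixed_dataset):
        """KPCA with a linear kernel reproduces the PCA test p-value."""
        G, y = _xy(fixed_dataset)
        res_k = kpca_test(G, y, TestConfig(kernel="linear"))
        res_p = pca_test(G, y)
        assert res_k.n_components == res_p.n_components
        assert res_k.p_value == pytest.approx(res_p.p_value, abs=1e-8)

    def test_permuted_phenotype_pvalues_uniformish(self, null_dataset):
        G, y = _xy(null_dataset)
        rng = np.random.default_rng(5)
        pvals = [kpca_test(G, rng.permutation(y)).p_value for _ in range(120)]
        assert stats.kstest(pvals, "uniform").pvalue > 1e-4

    def test_component_cap_flagged(self):
        rng = np.random.default_rng(6)
        y = rng.permutation(np.r_[np.ones(30), np.zeros(30)])
        X = rng.standard_normal((60, 40))  # high-dim noise: slow eigen decay
        res = kpca_test(X, y, TestConfig(kernel_bandwidth=0.5))
        assert res.n_components <= min(60 - 2, 50)


class TestSIR:
    def test_equal_slice_means_give_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 4))
        X = np.vstack([X, X])
        y = np.r_[np.ones(100), np.zeros(100)]  # identical groups
        eig = sir_eigen(X, y)
        assert np.allclose(eig.eigenvalues, 0.0, atol=1e-20)

    def test_rank_one_closed_form(self, fixed_dataset):
        """H=2: lambda_1 = p0*p1*||zbar_1 - zbar_0||^2 in standardised coords."""
        G, y = _xy(fixed_dataset)
        eig = sir_eigen(G, y)
        p1 = y.mean()
        diff = eig.slice_means[1] - eig.slice_means[0]
        lam = p1 * (1 - p1) * diff @ diff
        assert eig.eigenvalues[0] == pytest.approx(lam, abs=1e-10)
        assert eig.eigenvalues[1:].max() < 1e-10  # rank one
        assert eig.eigenvalues[0] <= 1.0

    def test_hotelling_closed_form(self, fixed_dataset):
        """T = n*p0*p1*(xbar1-xbar0)' Sigma^{-1} (xbar1-xbar0), to 1e-8."""
        G, y = _xy(fixed_dataset)
        res = sir_test(G, y)
        n = len(y)
        d = G[y == 1].mean(axis=0) - G[y == 0].mean(axis=0)
        Gc = G - G.mean(axis=0)
        S = Gc.T @ Gc / (n - 1)
        T = n * y.mean() * (1 - y.mean()) * d @ np.linalg.solve(S, d)
        assert res.statistic == pytest.approx(T, abs=1e-8)
        assert res.df == 10

    def test_single_class_rejected(self):
        X = np.random.default_rng(1).integers(0, 3, (50, 3)).astype(float)
        with pytest.raises(ValueError):
            sir_test(X, np.zeros(50))

    def test_near_singular_covariance_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, (200, 1)).astype(float)
        X = np.hstack([x, x, rng.integers(0, 3, (200, 2)).astype(float)])
        y = rng.permutation(np.r_[np.ones(100), np.zeros(100)])
        res = sir_test(X, y)
        assert res.diagnostics["pinv_clipped"]
        assert res.diagnostics["cov_rank"] < 4
        assert res.df == 4  # df stays at full p


class TestSingleSNP:
    def test_duplicated_snps_identical_p(self, null_dataset):
        G, y = _xy(null_dataset)
        G2 = np.hstack([G, G[:, [0]]])
        res = single_snp_tests(G2, y)
        assert res[0].p_value == pytest.approx(res[-1].p_value, abs=1e-9)

    def test_binary_genotype_matches_table_deviance(self):
        from tests.test_glm import _table_deviance, _table_to_xy

        x, y = _table_to_xy(40, 25, 22, 41)
        res = single_snp_tests(x[:, None], y)
        assert res[0].statistic == pytest.approx(
            _table_deviance(40, 25, 22, 41), abs=1e-6
        )

    def test_null_pvalues_uniform(self, null_dataset):
        G, y = _xy(null_dataset)
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(60):
            for r in single_snp_tests(G, rng.permutation(y)):
                pvals.append(r.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestInvariances:
    """Row- and column-permutation invariance of the four tests."""

    @pytest.mark.parametrize("method", ["pca", "kpca", "sir"])
    def test_row_permutation_invariance(self, fixed_dataset, method):
        from snpset import run_set_tests

        G, y = _xy(fixed_dataset)
        perm = np.random.default_rng(4).permutation(len(y))
        r1 = run_set_tests(G, y, [method])[method]
        r2 = run_set_tests(G[perm], y[perm], [method])[method]
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-8)

    @pytest.mark.parametrize("method", ["pca", "kpca", "sir"])
    def test_column_permutation_invariance(self, fixed_dataset, method):
        from snpset import run_set_tests

        G, y = _xy(fixed_dataset)
        cols = np.random.default_rng(5).permutation(G.shape[1])
        r1 = run_set_tests(G, y, [method])[method]
        r2 = run_set_tests(G[:, cols], y, [method])[method]
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-8)

    def test_spca_column_permutation_same_statistic(self, fixed_dataset):
        G, y = _xy(fixed_dataset)
        cols = np.random.default_rng(6).permutation(G.shape[1])
        cfg = TestConfig(n_permutations=100)
        r1 = spca_test(G, y, cfg, np.random.default_rng(0))
        r2 = spca_test(G[:, cols], y, cfg, np.random.default_rng(0))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-8)
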