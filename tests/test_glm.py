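"""Likelihood, gradients, analytic chi updates, and fitting."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

from elonglm.features import FeatureMatrix, standardize
from elonglm.glm import (
    GeneData,
    estimate_lambda,
    estimate_rho,
    fit,
    fit_lasso,
    fit_seqbias,
    gradient_kappa,
    heldout_loglik,
    local_rate,
    log_likelihood,
    predict_counts,
    predict_rates,
    select_nu,
    split_genes,
    sufficient_stats,
    update_chi,
)


def identity_matrix(p, n):
    """Dense feature matrix flagged as already standardized (tests drive it
    with explicit values)."""
    return FeatureMatrix([f"f{i}" for i in range(p)], np.zeros((n, p)),
                         mu=np.zeros(p), sigma=np.ones(p), mode="dense")


class TestLocalRate:
    def test_zero_kappa_gives_unit_rate(self, rng):
        y = rng.normal(size=(10, 4))
        np.testing.assert_array_equal(local_rate(np.zeros(4), y), 1.0)

    def test_intercept_only(self):
        assert local_rate(np.array([np.log(2.0), 0.0]),
                          np.array([1.0, 0.0])) == pytest.approx(2.0)

    def test_methylation_scaling(self):
        # a negative coefficient multiplies the rate by exp(kappa * z)
        z = 1.7
        base = local_rate(np.array([0.0, 0.0]), np.array([1.0, 0.0]))
        at_cpg = local_rate(np.array([0.0, -0.20]), np.array([1.0, z]))
        assert at_cpg / base == pytest.approx(np.exp(-0.20 * z))

    def test_dimension_error(self):
        with pytest.raises(ValueError):
            local_rate(np.zeros(3), np.zeros((5, 4)))


class TestLogLikelihood:
    def test_hand_value(self):
        genes = [GeneData("g", np.array([1.0, 1.0]))]
        m = identity_matrix(1, 2)
        # s log(chi) - kappa.T - chi U = 0 - 0 - 2
        assert log_likelihood(genes, m, np.zeros(2), np.array([1.0])) == -2.0

    def test_matches_poisson_pmf_oracle(self, poisson_gene_factory, rng):
        """Differences of the dropped-constant log likelihood across parameter
        settings equal differences of the full position-by-position Poisson
        log-pmf (the omitted terms are parameter-independent)."""
        genes, matrix, _ = poisson_gene_factory([0.0, 0.2, -0.3], n_genes=2,
                                                length=25)

        def full_ll(kappa, chi):
            total = 0.0
            off = 0
            for j, g in enumerate(genes):
                y = matrix.to_dense_standardized()[off : off + len(g)]
                mean = chi[j] * np.exp(-(y @ kappa))
                total += poisson.logpmf(g.counts.astype(int), mean).sum()
                off += len(g)
            return total

        settings = [(rng.normal(scale=0.3, size=3), rng.uniform(0.5, 2, 2))
                    for _ in range(3)]
        ours = [log_likelihood(genes, matrix, k, c) for k, c in settings]
        oracle = [full_ll(k, c) for k, c in settings]
        diffs_ours = np.diff(ours)
        diffs_oracle = np.diff(oracle)
        np.testing.assert_allclose(diffs_ours, diffs_oracle, rtol=1e-9)

    def test_intercept_only_profile(self, rng):
        counts = [rng.poisson(2.0, 30).astype(float) for _ in range(3)]
        genes = [GeneData(f"g{i}", c) for i, c in enumerate(counts)]
        m = identity_matrix(1, 90)
        s = np.array([c.sum() for c in counts])
        n = np.array([30.0] * 3)
        chi = s / n
        expected = float(np.sum(s * np.log(chi) - s))
        assert log_likelihood(genes, m, np.zeros(2), chi) == pytest.approx(expected)

    def test_chi_must_be_positive(self):
        genes = [GeneData("g", np.array([1.0]))]
        with pytest.raises(ValueError):
            log_likelihood(genes, identity_matrix(1, 1), np.zeros(2),
                           np.array([-1.0]))


class TestGradient:
    def test_hand_value(self):
        genes = [GeneData("g", np.array([2.0, 0.0, 1.0, 1.0]))]
        m = FeatureMatrix(["f"], np.array([[1.0], [0.0], [0.0], [1.0]]),
                          mu=np.zeros(1), sigma=np.ones(1), mode="dense")
        grad = gradient_kappa(genes, m, np.zeros(2), np.array([1.0]))
        # chi * sum(e^0 * Y) - sum(X * Y) = 2 - 3 = -1 for the feature
        assert grad[1] == pytest.approx(-1.0)

    def test_matches_finite_differences(self, poisson_gene_factory, rng):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.1, -0.2, 0.05],
                                                n_genes=3, length=30)
        h = 1e-6
        for _ in range(10):
            kappa = rng.normal(scale=0.3, size=4)
            chi = rng.uniform(0.5, 2.0, 3)
            grad = gradient_kappa(genes, matrix, kappa, chi)
            fd = np.empty_like(grad)
            for i in range(kappa.size):
                up, dn = kappa.copy(), kappa.copy()
                up[i] += h
                dn[i] -= h
                fd[i] = (log_likelihood(genes, matrix, up, chi)
                         - log_likelihood(genes, matrix, dn, chi)) / (2 * h)
            np.testing.assert_allclose(grad, fd, rtol=1e-6, atol=1e-6)

    def test_intercept_stationary_at_profile_optimum(self, rng):
        counts = rng.poisson(1.5, 40).astype(float)
        genes = [GeneData("g", counts)]
        m = identity_matrix(2, 40)
        chi = np.array([counts.mean()])
        grad = gradient_kappa(genes, m, np.zeros(3), chi)
        assert grad[0] == pytest.approx(0.0, abs=1e-10)


class TestUpdateChi:
    def test_zero_kappa_gives_mean_count(self, rng):
        counts = rng.poisson(2.0, 50).astype(float)
        chi = update_chi(np.array([counts.sum()]), np.array([50.0]))
        assert chi[0] == pytest.approx(counts.mean())

    def test_agrees_with_numeric_1d_maximization(self, poisson_gene_factory, rng):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.3], n_genes=1, length=20)
        kappa = rng.normal(scale=0.2, size=2)
        stats = sufficient_stats(genes, matrix, kappa)
        analytic = update_chi(stats.s, stats.U)[0]

        def neg(chi):
            return -log_likelihood(genes, matrix, kappa, np.array([chi]))

        numeric = minimize_scalar(neg, bounds=(1e-6, 50.0), method="bounded",
                                  options={"xatol": 1e-12}).x
        assert analytic == pytest.approx(numeric, abs=1e-6)
        # the analytic value attains (or exceeds) the numeric optimum
        assert -neg(analytic) >= -neg(numeric) - 1e-10
        # stationarity s - chi*U = 0 holds exactly
        assert stats.s[0] - analytic * stats.U[0] == pytest.approx(0.0, abs=1e-12)

    def test_doubling_counts_doubles_chi(self, rng):
        s = np.array([10.0, 4.0])
        u = rng.uniform(5, 20, 2)
        np.testing.assert_allclose(update_chi(2 * s, u), 2 * update_chi(s, u))

    def test_zero_count_gene_warns(self):
        with pytest.warns(UserWarning, match="zero total counts"):
            chi = update_chi(np.array([0.0]), np.array([5.0]))
        assert chi[0] == 0.0


class TestEstimators:
    def test_lambda_examples(self):
        assert estimate_lambda([GeneData("a", np.ones(4))]) == 1.0
        two = [GeneData("a", np.full(2, 2.0)), GeneData("b", np.zeros(2))]
        assert estimate_lambda(two) == 1.0

    def test_lambda_random_oracle(self, rng):
        counts = [rng.poisson(1.0, rng.integers(10, 50)).astype(float)
                  for _ in range(5)]
        genes = [GeneData(f"g{i}", c) for i, c in enumerate(counts)]
        flat = np.concatenate(counts)
        assert estimate_lambda(genes) == pytest.approx(flat.mean())

    def test_rho_examples(self):
        np.testing.assert_allclose(estimate_rho(list("ACGT" * 5)), 1.0)
        np.testing.assert_allclose(
            estimate_rho(["A"] * 10 + ["C"] * 20 + ["G"] * 30 + ["T"] * 40),
            [0.4, 0.8, 1.2, 1.6])
        with pytest.warns(UserWarning):
            rho = estimate_rho(["C"] * 8)
        assert rho[1] == pytest.approx(4.0)
        assert np.all(rho > 0)
        with pytest.raises(ValueError):
            estimate_rho([])


class TestFit:
    def test_intercept_only(self, rng):
        counts = [rng.poisson(3.0, 60).astype(float) for _ in range(4)]
        genes = [GeneData(f"g{i}", c) for i, c in enumerate(counts)]
        res = fit(genes, identity_matrix(1, 240))
        assert res.params.kappa[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.params.chi,
                                   [c.mean() for c in counts], rtol=1e-6)

    def test_matches_grid_search(self, rng):
        """Gradient-ascent optimum vs a dense grid over the two coefficients
        (chi profiled out at every grid point)."""
        n = 20
        Y = rng.standard_normal((n, 2))
        m = FeatureMatrix(["a", "b"], Y, mu=np.zeros(2), sigma=np.ones(2),
                          mode="dense")
        counts = rng.poisson(np.exp(-(Y @ [0.4, -0.5]))).astype(float)
        counts[0] = max(counts[0], 1.0)
        genes = [GeneData("g", counts)]

        def profile_obj(k1, k2):
            kappa = np.array([0.0, k1, k2])
            e = np.exp(-(Y @ [k1, k2]))
            chi = np.array([counts.sum() / e.sum()])
            return log_likelihood(genes, m, kappa, chi)

        grid = np.linspace(-1, 1, 81)
        best = max(profile_obj(a, b) for a in grid for b in grid)
        res = fit(genes, m, tol=1e-12)
        assert res.objective_trace[-1] >= best - 1e-3

    def test_recovery_consistency(self, rng):
        """kappa_hat approaches kappa_true as the number of positions grows
        (model-generated data, no simulator noise)."""
        from tests.conftest import make_poisson_genes

        kappa_true = np.array([0.0, 0.3, -0.2])
        rmses = []
        for length in (250, 1000, 4000):
            genes, matrix, _ = make_poisson_genes(kappa_true, 4, length,
                                                  np.random.default_rng(7))
            res = fit(genes, matrix)
            rmses.append(float(np.sqrt(np.mean(
                (res.params.kappa[1:] - kappa_true[1:]) ** 2))))
        assert rmses[2] < rmses[1] < rmses[0]

    def test_objective_monotone_at_fixed_learning_rate(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.2, -0.1], n_genes=2,
                                                length=50)
        res = fit(genes, matrix, learning_rate=1e-7, adaptive=False,
                  max_iter=2000, tol=0.0)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs >= -1e-9 * (np.abs(res.objective_trace[:-1]) + 1))


class TestLasso:
    def test_nu_zero_equals_unpenalized(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.25, -0.15], n_genes=2,
                                                length=60)
        plain = fit(genes, matrix, tol=1e-11)
        lasso = fit_lasso(genes, matrix, 0.0, tol=1e-11)
        assert abs(plain.objective_trace[-1]
                   - lasso.objective_trace[-1]) <= 1e-8

    def test_huge_nu_shrinks_everything(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.25, -0.15], n_genes=2,
                                                length=60)
        res = fit_lasso(genes, matrix, 1e7)
        np.testing.assert_array_equal(res.params.kappa[1:], 0.0)
        assert res.nonzero_features == []

    def test_subgradient_mode_close_to_prox(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.4, -0.3], n_genes=2,
                                                length=80)
        nu = 3.0
        prox = fit_lasso(genes, matrix, nu, tol=1e-11)
        sub = fit_lasso(genes, matrix, nu, l1_mode="subgradient", tol=1e-11)
        assert abs(prox.objective_trace[-1]
                   - sub.objective_trace[-1]) < 1e-2

    def test_penalized_trace_monotone(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.3], n_genes=2, length=50)
        res = fit_lasso(genes, matrix, 2.0, learning_rate=1e-7, adaptive=False,
                        max_iter=2000, tol=0.0)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs >= -1e-9 * (np.abs(res.objective_trace[:-1]) + 1))


class TestSelectNu:
    def test_single_value_grid(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.2], n_genes=5, length=30)
        nu, res, table = select_nu(genes, matrix, nu_grid=[1.5], seed=0)
        assert nu == 1.5
        assert len(table) == 1

    def test_null_truth_selects_empty_model(self, rng):
        from tests.conftest import make_poisson_genes

        genes, matrix, _ = make_poisson_genes(np.array([0.0, 0.0, 0.0]), 20, 400,
                                              rng)
        nu, res, table = select_nu(genes, matrix, seed=1, refit=False)
        assert nu == table["nu"].max()  # sparsest grid value wins
        assert len(res.nonzero_features) == 0

    def test_degenerate_split_errors(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.1], n_genes=1, length=30)
        with pytest.raises(ValueError):
            select_nu(genes, matrix, nu_grid=[1.0], seed=0)

    def test_split_is_deterministic(self):
        a = split_genes(50, 0.2, 3)
        b = split_genes(50, 0.2, 3)
        np.testing.assert_array_equal(a[0], b[0])
        assert len(a[1]) == 10


class TestSeqBias:
    def test_uniform_rho_reproduces_fit_exactly(self, poisson_gene_factory, rng):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.2, -0.1], n_genes=2,
                                                length=40)
        bases = rng.integers(0, 4, size=80)
        plain = fit(genes, matrix)
        biased = fit_seqbias(genes, matrix, np.ones(4), bases)
        np.testing.assert_array_equal(plain.params.kappa, biased.params.kappa)
        np.testing.assert_array_equal(plain.objective_trace,
                                      biased.objective_trace)

    def test_bias_correction_shrinks_spurious_base_coefficient(self, rng):
        """Counts enriched at C purely by protocol bias: the plain fit blames
        the C indicator, the bias-aware fit (with matching rho) does not."""
        n_genes, length = 6, 400
        seqs = rng.integers(0, 4, size=(n_genes, length))
        rho = np.array([1.0, 2.2, 1.0, 1.0])  # C over-represented
        rho = 4 * rho / rho.sum()
        genes = []
        for j in range(n_genes):
            mean = 2.0 * rho[seqs[j]]  # flat rate; counts follow the bias only
            genes.append(GeneData(f"g{j}", rng.poisson(mean).astype(float)))
        is_c = (seqs.reshape(-1) == 1).astype(float)[:, None]
        matrix = standardize(FeatureMatrix(["C"], is_c))
        plain = fit(genes, matrix)
        corrected = fit_seqbias(genes, matrix, rho, seqs.reshape(-1))
        assert plain.params.kappa[1] < -0.05  # bias masquerades as slow C
        assert abs(corrected.params.kappa[1]) < abs(plain.params.kappa[1]) / 3

    def test_input_validation(self, poisson_gene_factory, rng):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.1], n_genes=1, length=10)
        with pytest.raises(ValueError):
            fit_seqbias(genes, matrix, np.ones(3), np.zeros(10, int))
        with pytest.raises(ValueError):
            fit_seqbias(genes, matrix, np.ones(4), np.zeros(7, int))


class TestPrediction:
    def test_flat_model_predicts_chi(self, rng):
        m = identity_matrix(1, 30)
        zeta = predict_rates(np.zeros(2), m)
        np.testing.assert_array_equal(zeta, 1.0)
        np.testing.assert_array_equal(predict_counts(2.5, zeta), 2.5)

    def test_single_position_hand_check(self):
        m = FeatureMatrix(["a"], np.array([[1.5]]), mu=np.zeros(1),
                          sigma=np.ones(1), mode="dense")
        kappa = np.array([0.1, -0.4])
        assert predict_rates(kappa, m)[0] == pytest.approx(np.exp(0.1 - 0.6))


class TestMaskingAndSparseStats:
    def test_masked_positions_excluded_from_stats(self, rng):
        counts = rng.poisson(1.0, 50).astype(float)
        mask = np.ones(50, bool)
        mask[10:20] = False
        poisoned = counts.copy()
        poisoned[10:20] = 1e6  # sentinel values under the mask
        m = identity_matrix(1, 50)
        g_clean = [GeneData("g", counts, mask=mask)]
        g_poison = [GeneData("g", poisoned, mask=mask)]
        k, chi = np.zeros(2), np.array([1.0])
        assert log_likelihood(g_clean, m, k, chi) == log_likelihood(
            g_poison, m, k, chi)

    def test_sparse_and_dense_sufficient_stats_agree(self, rng):
        raw = sp.random(200, 8, density=0.15, random_state=3, format="csr")
        raw.data[:] = 1.0
        cols = [f"k{i}" for i in range(8)]
        genes = [GeneData("a", rng.poisson(0.5, 120).astype(float)),
                 GeneData("b", rng.poisson(0.5, 80).astype(float))]
        kappa = rng.normal(scale=0.2, size=9)
        st_sparse = sufficient_stats(genes, standardize(FeatureMatrix(cols, raw)),
                                     kappa)
        st_dense = sufficient_stats(genes,
                                    standardize(FeatureMatrix(cols, raw.toarray())),
                                    kappa)
        np.testing.assert_allclose(st_sparse.U, st_dense.U, atol=1e-10)
        np.testing.assert_allclose(st_sparse.V, st_dense.V, atol=1e-10)
        np.testing.assert_allclose(st_sparse.T, st_dense.T, atol=1e-10)

    def test_heldout_loglik_refits_chi(self, poisson_gene_factory):
        genes, matrix, _ = poisson_gene_factory([0.0, 0.2], n_genes=2, length=40)
        ll = heldout_loglik(genes, matrix, np.zeros(2))
        s = np.array([g.s for g in genes])
        n = np.array([float(len(g)) for g in genes])
        expected = float(np.sum(s * np.log(s / n) - s))
        assert ll == pytest.approx(expected)
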