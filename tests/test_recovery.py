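"""Recovery procedures: residual variance, basic/weighted/refit/robust, helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allocov.equations import BiomassEquation, FitStats, get_equation, trees_to_arrays
from allocov.exceptions import (
    DegenerateSampleError,
    InputError,
    NoSolutionError,
    UnsupportedCaseError,
)
from allocov.recovery import (
    BasicRecovery,
    RecoveryConfig,
    basic_recovery,
    make_psd,
    mc_error_monitor,
    offdiagonal_recovery,
    recover_residual_variance,
    refit_recovery,
    robust_recovery,
    solve_gamma_nu,
    weighted_recovery,
)

from conftest import make_trees


class TestResidualVariance:
    def test_frozen_guazuma_case(self, guazuma):
        """Log-scale predictions at D=10,20,30 have sample variance 1.38712...;
        times (1/0.97 - 1) gives the recovered residual variance."""
        eq, _ = guazuma
        trees = make_trees([10.0, 20.0, 30.0])
        assert recover_residual_variance(eq, trees, 0.97) == pytest.approx(
            0.0429007607051933, rel=1e-12)

    def test_perfect_fit_gives_zero(self, beech):
        eq, _ = beech
        trees = make_trees([10, 20, 30], [10, 15, 20])
        assert recover_residual_variance(eq, trees, 1.0) == 0.0

    def test_half_r2_equals_prediction_variance(self, beech):
        eq, _ = beech
        trees = make_trees([10, 20, 30], [10, 15, 20])
        from allocov.equations import predict_fitted_scale
        v = np.var(predict_fitted_scale(eq, trees), ddof=1)
        assert recover_residual_variance(eq, trees, 0.5) == pytest.approx(v)

    def test_identical_trees_degenerate(self, beech):
        eq, _ = beech
        with pytest.raises(DegenerateSampleError):
            recover_residual_variance(eq, make_trees([20, 20], [15, 15]), 0.9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(r2=st.floats(0.05, 0.999))
    def test_monotone_decreasing_in_r2(self, beech, r2):
        """Recovered sigma2 strictly decreases as R2 increases, all else fixed."""
        eq, _ = beech
        trees = make_trees([12, 25, 37, 50], [10, 18, 24, 30])
        lo = recover_residual_variance(eq, trees, r2)
        hi = recover_residual_variance(eq, trees, min(r2 + 1e-3, 1.0))
        assert lo > hi


class TestSolveGammaNu:
    def test_algebra(self):
        assert solve_gamma_nu(2.0, 1.0, 2.0) == pytest.approx(5.0)

    def test_limit_variance_to_zero(self):
        # as target variance approaches the prediction variance, nu explodes
        assert solve_gamma_nu(2.0, 1.0, 1.0 + 1e-12) > 1e11

    def test_no_real_solution(self):
        with pytest.raises(NoSolutionError):
            solve_gamma_nu(2.0, 1.0, 0.5)

    def test_monte_carlo_product_variance(self):
        """Empirical V(y*e) for e~gamma(5, 1/5) matches the first-order formula."""
        rng = np.random.default_rng(99)
        y = rng.uniform(1.0, 3.0, size=200)
        nu = 5.0
        e = rng.gamma(nu, 1.0 / nu, size=(5000, 200))
        emp = np.var((y * e).ravel(), ddof=1)
        expected = np.var(y, ddof=1) + (y.mean() ** 2 + np.var(y, ddof=1)) / nu
        assert emp == pytest.approx(expected, rel=0.02)


class TestBasicRecovery:
    def test_single_replicate_is_definition(self, beech):
        """With the population equal to the sample, one replicate reproduces
        sigma2 (FtF)^-1 exactly."""
        eq, _ = beech
        trees = make_trees([12, 25, 37, 50, 61], [10, 18, 24, 30, 33])
        fit = FitStats(n=5, r_squared=0.9)
        stats = basic_recovery(eq, trees, fit, RecoveryConfig(B=1, n=5, seed=0))
        from allocov.equations import gradient_matrix, predict_fitted_scale
        F = gradient_matrix(eq, trees).values
        s2 = np.var(predict_fitted_scale(eq, trees), ddof=1) * (1 / 0.9 - 1)
        assert stats.sigma2_resid == pytest.approx(s2, rel=1e-12)
        assert np.allclose(stats.cov, s2 * np.linalg.inv(F.T @ F), rtol=1e-10)

    def test_orthonormal_design_scalar(self):
        """y = b*x with sum x^2 = 1: covariance collapses to [[sigma2]]."""
        eq = BiomassEquation("unit", "linear-in-basis", (1.0,), basis=("dbh",))
        x = np.array([0.6, 0.8])
        trees = make_trees(x)
        fit = FitStats(n=2, r_squared=0.5)
        stats = basic_recovery(eq, trees, fit, RecoveryConfig(B=1, n=2, seed=0))
        assert stats.cov.shape == (1, 1)
        assert stats.cov[0, 0] == pytest.approx(stats.sigma2_resid, rel=1e-12)

    def test_brute_force_oracle(self, beech, beech_population):
        """Element-wise agreement with an independent per-sample OLS-covariance
        loop on the same seeded replicate draws."""
        eq, fs = beech
        pop = list(beech_population)[:400]
        cfg = RecoveryConfig(B=50, seed=11)
        stats = basic_recovery(eq, pop, fs, cfg)
        # independent re-implementation: plain loops and textbook formulas
        dbh = np.array([t.dbh_cm for t in pop])
        ht = np.array([t.ht_m for t in pop])
        children = np.random.SeedSequence(11).spawn(50)
        acc = np.zeros((2, 2))
        s_acc = 0.0
        for ch in children:
            r = np.random.default_rng(ch)
            idx = r.choice(len(pop), size=fs.n, replace=False)
            X = np.column_stack([dbh[idx] ** 2, np.sqrt(dbh[idx] * ht[idx])])
            pred = X @ np.array(eq.coefficients)
            s2 = pred.var(ddof=1) * (1 / fs.r_squared - 1)
            acc += s2 * np.linalg.inv(X.T @ X)
            s_acc += s2
        assert np.allclose(stats.cov, acc / 50, rtol=1e-9)
        assert stats.sigma2_resid == pytest.approx(s_acc / 50, rel=1e-12)

    def test_population_smaller_than_n(self, beech):
        eq, fs = beech
        with pytest.raises(InputError):
            basic_recovery(eq, make_trees([10, 20], [10, 12]), fs, RecoveryConfig(B=2))

    def test_generalized_equation_refused(self, beech_population):
        eq, fs = get_equation("beech_generalized_13")
        with pytest.raises(UnsupportedCaseError):
            basic_recovery(eq, list(beech_population), fs, RecoveryConfig(B=2))

    def test_seed_determinism_byte_identical(self, beech, beech_population):
        eq, fs = beech
        pop = list(beech_population)[:500]
        a = basic_recovery(eq, pop, fs, RecoveryConfig(B=20, seed=5))
        b = basic_recovery(eq, pop, fs, RecoveryConfig(B=20, seed=5))
        assert a.sigma2_resid == b.sigma2_resid
        assert np.array_equal(a.cov, b.cov)

    def test_substreams_extend_with_B(self, beech, beech_population):
        """Raising B appends replicates without reshuffling earlier ones."""
        eq, fs = beech
        pop = list(beech_population)[:500]
        small = basic_recovery(eq, pop, fs, RecoveryConfig(B=10, seed=5))
        large = basic_recovery(eq, pop, fs, RecoveryConfig(B=25, seed=5))
        assert np.array_equal(small.per_replicate_dets,
                              large.per_replicate_dets[:10])

    def test_returned_cov_symmetric_psd(self, beech, beech_population):
        eq, fs = beech
        stats = basic_recovery(eq, list(beech_population)[:500], fs,
                               RecoveryConfig(B=30, seed=2))
        assert np.array_equal(stats.cov, stats.cov.T)
        assert np.all(np.linalg.eigvalsh(stats.cov) >= 0)

    def test_sklearn_estimator_interface(self, beech, beech_population):
        eq, fs = beech
        est = BasicRecovery(equation=eq, fit_stats=fs, B=5, seed=1)
        assert est.get_params()["B"] == 5
        est.set_params(B=7).fit(list(beech_population)[:300])
        assert est.B_used_ == 7
        assert est.cov_.shape == (2, 2)
        assert est.results_.method == "basic"


class TestWeightedRecovery:
    def test_equal_dbh_matches_uniform_weight_scaling(self):
        """All-equal DBH collapses W to (1/n) I, so (FtWF)^-1 = n (FtF)^-1."""
        eq = BiomassEquation("w", "linear-in-basis", (1.0, 1.0),
                             basis=("dbh^2", "sqrt(ht)"),
                             weight_rule="inverse-dbh-squared")
        trees = make_trees([20, 20, 20, 20], [10, 15, 20, 25])
        fit = FitStats(n=4, r_squared=0.8)
        w = weighted_recovery(eq, trees, fit, RecoveryConfig(B=1, n=4, seed=0))
        b = basic_recovery(eq, trees, fit, RecoveryConfig(B=1, n=4, seed=0))
        assert np.allclose(w.cov, 4.0 * b.cov, rtol=1e-10)

    def test_two_tree_weight_normalization(self):
        # 1/100 and 1/400 normalize to 0.8 and 0.2
        from allocov.recovery import _normalized_weights
        w = _normalized_weights(None, np.array([10.0, 20.0]))
        assert np.allclose(w, [0.8, 0.2])

    def test_pps_inclusion_weights_hand_case(self, beech):
        """Three trees with inclusion probabilities (0.2, 0.3, 0.5): weights
        are inverse probabilities normalized; covariance matches the
        hand-built (Ft W F)^-1 scaled by sigma2."""
        eq, _ = beech
        trees = make_trees([10.0, 20.0, 40.0], [8.0, 14.0, 28.0])
        fit = FitStats(n=3, r_squared=0.9)
        incl = np.array([0.2, 0.3, 0.5])
        stats = weighted_recovery(eq, trees, fit, RecoveryConfig(B=1, n=3, seed=0),
                                  inclusion_weights=1.0 / incl)
        w = (1 / incl) / (1 / incl).sum()
        dbh, ht = trees_to_arrays(trees)
        F = np.column_stack([dbh**2, np.sqrt(dbh * ht)])
        pred = F @ np.array(eq.coefficients)
        s2 = pred.var(ddof=1) * (1 / 0.9 - 1)
        expected = s2 * np.linalg.inv(F.T @ np.diag(w) @ F)
        assert np.allclose(stats.cov, expected, rtol=1e-10)

    def test_unweighted_equation_refused(self, beech, beech_population):
        eq, fs = beech  # beech_1 has weight_rule none
        with pytest.raises(InputError):
            weighted_recovery(eq, list(beech_population)[:200], fs,
                              RecoveryConfig(B=1))


class TestRobustRecovery:
    def test_homoscedastic_sandwich_collapse(self):
        """With constant squared residuals the sandwich reduces to
        sigma2 (FtF)^-1 — the algebraic identity behind the estimator."""
        rng = np.random.default_rng(0)
        F = rng.uniform(1, 5, size=(20, 2))
        s2 = 0.7
        inv = np.linalg.inv(F.T @ F)
        meat = F.T @ (np.full(20, s2)[:, None] * F)
        assert np.allclose(inv @ meat @ inv, s2 * inv)

    def test_expectation_matches_basic(self, guazuma, guazuma_population):
        """E[e^2] = sigma2 makes the mean sandwich converge to the basic form."""
        eq, fs = guazuma
        pop = list(guazuma_population)[:200]
        basic = basic_recovery(eq, pop, fs, RecoveryConfig(B=300, seed=3))
        robust = robust_recovery(eq, pop, fs, RecoveryConfig(B=300, seed=3))
        assert np.allclose(robust.cov, basic.cov, rtol=0.10)

    def test_df_rule_and_too_small_n(self, guazuma, guazuma_population):
        eq, _ = guazuma
        pop = list(guazuma_population)[:50]
        fit = FitStats(n=5, r_squared=0.9)  # floor(0.5*5)=2 -> undefined t variance
        with pytest.raises(NoSolutionError, match="degrees of freedom"):
            robust_recovery(eq, pop, fit, RecoveryConfig(B=1, seed=0))

    def test_n6_uses_df3(self, guazuma, guazuma_population):
        eq, _ = guazuma
        fit = FitStats(n=6, r_squared=0.9)
        stats = robust_recovery(eq, list(guazuma_population)[:60], fit,
                                RecoveryConfig(B=50, seed=4))
        assert stats.cov.shape == (2, 2)
        assert np.all(np.diag(stats.cov) > 0)


class TestRefitRecovery:
    def test_noiseless_limit(self, beech, beech_population):
        """R2 = 1 gives zero residual scale: refit returns the coefficients
        exactly and a zero covariance matrix."""
        eq, _ = beech
        fit = FitStats(n=50, r_squared=1.0)
        stats = refit_recovery(eq, list(beech_population)[:300], fit,
                               RecoveryConfig(B=3, seed=1))
        assert stats.sigma2_resid == 0.0
        assert np.allclose(stats.cov, 0.0, atol=1e-18)

    def test_linear_t_residual_expectation(self, guazuma, guazuma_population):
        """Mean recovered covariance over many refits approximates
        sigma2 (XtX)^-1 on a fixed design (all-positive log-scale pseudo data
        never trigger the gamma fallback)."""
        eq, fs = guazuma
        trees = list(guazuma_population)[:40]
        cfg = RecoveryConfig(B=2000, n=40, seed=8)
        stats = refit_recovery(eq, trees, fs, cfg)
        basic = basic_recovery(eq, trees, fs, RecoveryConfig(B=1, n=40, seed=8))
        assert stats.gamma_fallback_count == 0
        assert np.allclose(stats.cov, basic.cov, rtol=0.10)

    def test_gamma_fallback_triggers_for_negative_pseudodata(self, beech_population):
        """beech_1 predicts slightly negative AGB for the smallest trees, so
        additive pseudo-residuals produce negative biomass and the replicate
        must switch to multiplicative gamma errors."""
        eq, fs = get_equation("beech_1")
        stats = refit_recovery(eq, list(beech_population)[:1000], fs,
                               RecoveryConfig(B=30, seed=6))
        assert stats.gamma_fallback_count > 0

    def test_no_fallback_when_predictions_far_from_zero(self, guazuma_population):
        eq, fs = get_equation("quercus_castenea")  # power form, positive preds
        mid = [t for t in guazuma_population if 15.0 <= t.dbh_cm <= 25.0]
        stats = refit_recovery(eq, mid[:60], FitStats(n=20, r_squared=0.97),
                               RecoveryConfig(B=30, seed=6))
        assert stats.gamma_fallback_count == 0


class TestOffdiagonalRecovery:
    def test_diagonal_is_se_squared(self, beech, beech_population):
        eq, _ = beech
        cov = offdiagonal_recovery(eq, list(beech_population)[:100], [0.05, 2.9])
        assert np.allclose(np.diag(cov), [0.05**2, 2.9**2])

    def test_collinear_gradients_full_correlation(self):
        """Both gradient components proportional to each other: corr 1 and the
        off-diagonal equals the geometric mean of the variances."""
        # perfect collinearity via two identical transforms of dbh
        eqp = BiomassEquation("p", "linear-in-basis", (1.0, 1.0),
                              basis=("dbh", "dbh"))
        trees = make_trees([10.0, 20.0, 30.0, 40.0])
        cov = offdiagonal_recovery(eqp, trees, [2.0, 3.0])
        assert cov[0, 1] == pytest.approx(6.0)

    def test_orthogonal_components_zero_offdiagonal(self):
        eq = BiomassEquation("o", "linear-in-basis", (1.0, 1.0),
                             basis=("1", "dbh"))
        # intercept gradient is constant -> zero variance -> undefined corr
        with pytest.raises(DegenerateSampleError):
            offdiagonal_recovery(eq, make_trees([10.0, 20.0, 30.0]), [1.0, 1.0])

    def test_pearson_against_numpy_oracle(self, beech, beech_population):
        eq, _ = beech
        trees = list(beech_population)[:200]
        se = [0.0512, 2.944]  # sqrt of Table-2-scale variances
        cov = offdiagonal_recovery(eq, trees, se)
        dbh = np.array([t.dbh_cm for t in trees])
        ht = np.array([t.ht_m for t in trees])
        r = np.corrcoef(dbh**2, np.sqrt(dbh * ht))[0, 1]
        assert cov[0, 1] == pytest.approx(r * se[0] * se[1], rel=1e-10)

    def test_robust_weighting_changes_but_preserves_structure(self, beech, beech_population):
        eq, _ = beech
        trees = list(beech_population)[:200]
        plain = offdiagonal_recovery(eq, trees, [0.05, 2.9], robust=False)
        rob = offdiagonal_recovery(eq, trees, [0.05, 2.9], robust=True,
                                   cfg=RecoveryConfig(seed=3, n=50))
        assert np.sign(rob[0, 1]) == np.sign(plain[0, 1])
        assert rob[0, 1] != plain[0, 1]
        assert np.allclose(np.diag(rob), np.diag(plain))


class TestMcErrorMonitor:
    def test_identical_replicates_zero(self):
        assert mc_error_monitor([1.0, 1.0, 1.0]) == 0.0

    def test_frozen_arithmetic(self):
        # dets (1,1,1,3): SD=1, mean=1.5, B=4 -> 100*(1/2)/1.5
        assert mc_error_monitor([1.0, 1.0, 1.0, 3.0]) == pytest.approx(100 / 3)

    def test_matrix_input(self):
        mats = [np.eye(2) * c for c in (1.0, 2.0)]
        dets = [1.0, 4.0]
        assert mc_error_monitor(mats) == pytest.approx(mc_error_monitor(dets))


class TestMakePsd:
    def test_indefinite_matrix_repaired(self):
        m = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        fixed, repaired = make_psd(m)
        assert repaired
        assert np.all(np.linalg.eigvalsh(fixed) >= -1e-12)

    def test_psd_matrix_untouched(self):
        m = np.array([[2.0, 0.5], [0.5, 1.0]])
        fixed, repaired = make_psd(m)
        assert not repaired
        assert np.allclose(fixed, m)
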