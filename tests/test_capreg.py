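"""CAP regression core: likelihood, update steps, DfD, order selection."""

import numpy as np
import pytest

import icacap as ic
from icacap.capreg import (
    CAPError,
    CAPRegression,
    SampleCovariance,
    dfd,
    fit_component,
    neg_log_likelihood,
    pooled_covariance,
    sample_covariance,
    select_R,
    update_beta,
    update_gamma,
    variance_explained,
)
from icacap.design import CovariateDesign


def _cov(M, T, id="s"):
    return SampleCovariance(Sigma_hat=np.asarray(M, dtype=float), T=T, id=id)


INTERCEPT_1 = CovariateDesign(np.ones((1, 1)), ["intercept"])
INTERCEPT_2 = CovariateDesign(np.ones((2, 1)), ["intercept"])
BINARY_2 = CovariateDesign(np.array([[1.0, 0.0], [1.0, 1.0]]), ["intercept", "x"])


class TestSampleCovariance:
    def test_matches_brute_force_on_tiny_matrix(self):
        A = ic.SubjectSeries(id="a", M=np.array([[1.0, 2.0], [3.0, 5.0], [5.0, 11.0]]))
        got = sample_covariance(A).Sigma_hat
        # brute force: centered cross products with divisor T
        M = A.M - A.M.mean(axis=0)
        expect = np.array(
            [
                [np.mean(M[:, 0] * M[:, 0]), np.mean(M[:, 0] * M[:, 1])],
                [np.mean(M[:, 1] * M[:, 0]), np.mean(M[:, 1] * M[:, 1])],
            ]
        )
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_duplicated_column_rank_deficient(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(50)
        A = ic.SubjectSeries(id="a", M=np.column_stack([col, col]))
        S = sample_covariance(A).Sigma_hat
        assert np.linalg.matrix_rank(S) == 1
        np.testing.assert_allclose(S[0, 1], S[0, 0], atol=1e-12)

    def test_orthogonal_unit_columns_give_identity(self):
        rng = np.random.default_rng(1)
        A = ic.SubjectSeries(id="a", M=rng.standard_normal((10000, 3)))
        S = sample_covariance(A).Sigma_hat
        np.testing.assert_allclose(S, np.eye(3), atol=0.08)

    def test_single_row_rejected(self):
        with pytest.raises(Exception):
            sample_covariance(ic.SubjectSeries(id="a", M=np.ones((1, 2))))


class TestNegLogLikelihood:
    def test_direct_formula_value(self):
        # one subject, T=10, gamma^T Sigma gamma = 1, beta = 0 -> 5.0
        val = neg_log_likelihood(
            np.array([1.0, 0.0]), np.zeros(1), [_cov(np.eye(2), 10)], INTERCEPT_1
        )
        assert val == pytest.approx(5.0, abs=1e-12)

    def test_intercept_stationarity(self):
        # beta0 = log(gamma^T Sigma gamma) is the intercept-only optimum
        covs = [_cov(np.diag([2.5, 1.0]), 10)]
        g = np.array([1.0, 0.0])
        b_star = np.array([np.log(2.5)])
        eps = 1e-6
        f0 = neg_log_likelihood(g, b_star - eps, covs, INTERCEPT_1)
        f1 = neg_log_likelihood(g, b_star, covs, INTERCEPT_1)
        f2 = neg_log_likelihood(g, b_star + eps, covs, INTERCEPT_1)
        assert f1 <= f0 and f1 <= f2

    def test_scaling_identity(self):
        # scaling all Sigma by c and shifting intercept by log c changes the
        # value by (1/2) sum T_i log c exactly
        rng = np.random.default_rng(3)
        M = rng.standard_normal((5, 3))
        covs = [_cov(M.T @ M / 5, 12)]
        g = np.array([0.3, -0.5, 0.8])
        b = np.array([0.2])
        c = 3.7
        covs_scaled = [_cov(c * covs[0].Sigma_hat, 12)]
        v1 = neg_log_likelihood(g, b, covs, INTERCEPT_1)
        v2 = neg_log_likelihood(g, b + np.log(c), covs_scaled, INTERCEPT_1)
        assert v2 - v1 == pytest.approx(0.5 * 12 * np.log(c), abs=1e-9)

    def test_overflow_guarded(self):
        with pytest.warns(UserWarning):
            v = neg_log_likelihood(
                np.array([1.0]),
                np.array([-1000.0]),
                [_cov([[1.0]], 10)],
                INTERCEPT_1,
            )
        assert v == np.inf


class TestUpdateBeta:
    def test_weighted_mean_intercept(self):
        # s = (1, 3), T = (10, 10) -> beta0 = log 2
        covs = [_cov(np.diag([1.0, 9.0]), 10, "a"), _cov(np.diag([3.0, 9.0]), 10, "b")]
        b = update_beta(np.array([1.0, 0.0]), covs, INTERCEPT_2)
        assert b[0] == pytest.approx(np.log(2.0), abs=1e-6)

    def test_binary_covariate_log_ratio(self):
        # group variances (1, e) -> slope 1, intercept 0
        covs = [_cov(np.diag([1.0, 1.0]), 10, "a"), _cov(np.diag([np.e, 1.0]), 10, "b")]
        b = update_beta(np.array([1.0, 0.0]), covs, BINARY_2)
        np.testing.assert_allclose(b, [0.0, 1.0], atol=1e-6)

    def test_constant_s_zeroes_effects(self, small_design):
        covs = [_cov(np.diag([2.0, 1.0]), 30, f"s{i}") for i in range(small_design.n)]
        b = update_beta(np.array([1.0, 0.0]), covs, small_design)
        np.testing.assert_allclose(b[1:], 0.0, atol=1e-8)
        assert b[0] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        d = CovariateDesign(X, ["intercept", "a", "b"])
        covs = [_cov(np.eye(2), 10, f"s{i}") for i in range(4)]
        with pytest.raises(CAPError):
            update_beta(np.array([1.0, 0.0]), covs, d)


class TestUpdateGamma:
    def test_single_direction(self):
        covs = [_cov([[4.0]], 10)]
        g = update_gamma(np.zeros(1), covs, INTERCEPT_1, metric=np.array([[4.0]]))
        assert abs(g[0]) == pytest.approx(0.5, abs=1e-10)  # 1/sqrt(metric)

    def test_diagonal_enumeration_oracle(self):
        # M = diag(20, 10 + 10/e): minimizing direction is e2
        covs = [_cov(np.diag([1.0, 1.0]), 10, "a"), _cov(np.diag([np.e, 1.0]), 10, "b")]
        g = update_gamma(np.array([0.0, 1.0]), covs, BINARY_2, metric=np.eye(2))
        np.testing.assert_allclose(np.abs(g), [0.0, 1.0], atol=1e-10)

    def test_beats_random_feasible_probes(self, random_psd_covs):
        rng = np.random.default_rng(7)
        n = len(random_psd_covs)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        d = CovariateDesign(X, ["intercept", "x"])
        H = pooled_covariance(random_psd_covs)
        beta = np.array([0.1, 0.3])
        prev_raw = rng.standard_normal(5)
        prev = [prev_raw / np.sqrt(prev_raw @ H @ prev_raw)]
        g = update_gamma(beta, random_psd_covs, d, prev=prev, metric=H)
        # constraints hold to 1e-10
        assert abs(g @ H @ g - 1.0) < 1e-10
        assert abs(g @ H @ prev[0]) < 1e-10
        # objective value
        Sig = np.stack([c.Sigma_hat for c in random_psd_covs])
        T = np.array([c.T for c in random_psd_covs], dtype=float)
        eta = X @ beta
        M = np.einsum("i,ijk->jk", T * np.exp(-eta), Sig)
        f_opt = g @ M @ g
        # 1000 random feasible probes never beat the eigen solution
        for _ in range(1000):
            v = rng.standard_normal(5)
            v -= prev[0] * (prev[0] @ H @ v)  # H-orthogonal to prev
            v /= np.sqrt(v @ H @ v)
            assert f_opt <= v @ M @ v + 1e-8

    def test_no_feasible_subspace_rejected(self):
        covs = [_cov(np.eye(2), 10)]
        with pytest.raises(CAPError):
            update_gamma(
                np.zeros(1),
                covs,
                INTERCEPT_1,
                prev=[np.array([1.0, 0.0]), np.array([0.0, 1.0])],
            )


class TestFitComponent:
    def test_recovers_true_projection(self, cap_dataset):
        comp = fit_component(cap_dataset["covs"], cap_dataset["design"], seed=0)
        cosang = abs(comp.gamma @ cap_dataset["model"].Gamma[:, 0])
        assert cosang > 0.9
        err = np.max(np.abs(comp.beta - cap_dataset["beta"][:, 0]))
        assert err < 0.2

    def test_objective_monotone_nonincreasing(self, cap_dataset):
        comp = fit_component(cap_dataset["covs"], cap_dataset["design"], seed=1)
        tr = comp.objective_trace
        assert np.all(np.diff(tr) <= 1e-8 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_null_data_gives_small_effects(self):
        # no covariate effect: non-intercept estimates center at zero
        beta0 = np.zeros((5, 1))
        ests = []
        for rep in range(24):
            d = ic.gen_covariates(60, (15, 15, 15, 15), seed=100 + rep)
            m = ic.gen_true_model(3, 1, beta0, seed=200 + rep)
            A = ic.gen_mixing_series(m, d, T=150, seed=300 + rep)
            covs = [ic.sample_covariance(a) for a in A]
            comp = fit_component(covs, d, seed=rep)
            ests.append(comp.beta[1:])
        # per-replicate estimates carry selection noise (the fitted gamma
        # maximizes apparent heteroscedasticity) but no directional bias
        mean_effect = np.mean(ests, axis=0)
        assert np.max(np.abs(mean_effect)) < 0.15

    def test_unit_norm_and_sign_canonical(self, cap_dataset):
        comp = fit_component(cap_dataset["covs"], cap_dataset["design"], seed=2)
        assert np.linalg.norm(comp.gamma) == pytest.approx(1.0, abs=1e-10)
        assert comp.gamma[np.argmax(np.abs(comp.gamma))] > 0

    def test_intercept_consistent_after_rescaling(self, cap_dataset):
        """Reported beta equals a fresh beta fit at the reported unit gamma."""
        comp = fit_component(cap_dataset["covs"], cap_dataset["design"], seed=3)
        b = update_beta(comp.gamma, cap_dataset["covs"], cap_dataset["design"])
        np.testing.assert_allclose(comp.beta, b, atol=1e-8)

    def test_small_T_rejected(self, small_design):
        covs = [
            _cov(np.eye(6), 5, f"s{i}") for i in range(small_design.n)
        ]  # T=5 < K=6
        with pytest.raises(CAPError):
            fit_component(covs, small_design, seed=0)


class TestEquivariance:
    def test_orthogonal_rotation_maps_gamma(self, cap_dataset):
        """Rotating the data by Q maps gamma to Q gamma (up to sign), beta fixed."""
        rng = np.random.default_rng(17)
        W = rng.standard_normal((4, 4))
        Q, _ = np.linalg.qr(W)
        covs_rot = [
            SampleCovariance(Q @ c.Sigma_hat @ Q.T, c.T, c.id)
            for c in cap_dataset["covs"]
        ]
        c0 = fit_component(cap_dataset["covs"], cap_dataset["design"], seed=4)
        c1 = fit_component(covs_rot, cap_dataset["design"], seed=4)
        assert abs(c1.gamma @ (Q @ c0.gamma)) == pytest.approx(1.0, abs=1e-4)
        np.testing.assert_allclose(c1.beta, c0.beta, atol=1e-3)


class TestDfD:
    def test_codiagonal_input_gives_one(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((4, 4))
        Q, _ = np.linalg.qr(W)
        covs = [
            _cov(Q @ np.diag(rng.uniform(0.5, 2.0, 4)) @ Q.T, 20, f"s{i}")
            for i in range(6)
        ]
        assert dfd(Q[:, :3], covs) == pytest.approx(1.0, abs=1e-8)

    def test_hand_computed_2x2(self):
        covs = [_cov([[1.0, 0.5], [0.5, 1.0]], 7)]
        assert dfd(np.eye(2), covs) == pytest.approx(1.0 / 0.75, abs=1e-12)

    def test_column_permutation_invariant(self, random_psd_covs):
        rng = np.random.default_rng(9)
        G = rng.standard_normal((5, 3))
        v1 = dfd(G, random_psd_covs)
        v2 = dfd(G[:, [2, 0, 1]], random_psd_covs)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_hadamard_lower_bound(self, random_psd_covs):
        rng = np.random.default_rng(10)
        for _ in range(50):
            G = rng.standard_normal((5, 3))
            assert dfd(G, random_psd_covs) >= 1.0 - 1e-12


class TestSelectR:
    def test_rule_application_by_hand(self):
        r = select_R(np.array([1.01, 1.02, 1.05, 1.80, 2.50]), tau=1.5, delta=0.2)
        assert r == 3

    def test_flat_trace_keeps_all(self):
        assert select_R(np.ones(6)) == 6

    def test_fallback_to_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert select_R(np.array([3.0, 4.0]), tau=1.5, delta=0.2) == 1


class TestVarianceExplained:
    def test_direct_ratio(self):
        covs = [_cov(np.diag([2.0, 2.0]), 10)]
        ve = variance_explained(np.array([1.0, 0.0]), covs)
        assert ve[0, 0] == pytest.approx(50.0, abs=1e-12)

    def test_full_basis_sums_to_100(self, random_psd_covs):
        ve = variance_explained(np.eye(5), random_psd_covs)
        np.testing.assert_allclose(ve.sum(axis=1), 100.0, atol=1e-8)

    def test_brute_force_quadratic_forms(self):
        rng = np.random.default_rng(11)
        W = rng.standard_normal((4, 4))
        Sigma = W @ W.T
        covs = [_cov(Sigma, 10)]
        G = rng.standard_normal((4, 2))
        G /= np.linalg.norm(G, axis=0)
        ve = variance_explained(G, covs)
        for c in range(2):
            expect = 100 * (G[:, c] @ Sigma @ G[:, c]) / np.trace(Sigma)
            assert ve[0, c] == pytest.approx(expect, rel=1e-10)


class TestFitCap:
    def test_codiagonal_trace_stays_one(self):
        rng = np.random.default_rng(12)
        covs = [
            _cov(np.diag(rng.uniform(0.5, 2.0, 4)), 30, f"s{i}") for i in range(10)
        ]
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        d = CovariateDesign(X, ["intercept", "x"])
        res = ic.fit_cap(covs, d, R_max=4)
        np.testing.assert_allclose(res.dfd_trace, 1.0, atol=1e-6)

    def test_components_metric_orthogonal(self, cap_dataset):
        model = CAPRegression(cap_dataset["A_list"], cap_dataset["design"])
        res = model.fit(R_max=3, seed=0)
        H = pooled_covariance(model.covs)
        G = res.Gamma_full
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(G[:, a] @ H @ G[:, b]) < 1e-8

    def test_two_components_recovered(self):
        """Distinct covariate signatures (gender vs alcohol) both recovered."""
        beta = np.array(
            [[0.1, -0.2], [0.0, 0.0], [0.0, -0.6], [0.7, 0.0], [0.0, 0.0]]
        )
        d = ic.gen_covariates(150, (37, 50, 22, 41), seed=50)
        m = ic.gen_true_model(K=5, R=2, beta=beta, seed=51)
        A = ic.gen_mixing_series(m, d, T=300, seed=52)
        covs = [ic.sample_covariance(a) for a in A]
        res = ic.fit_cap(covs, d, R_max=2)
        C = np.abs(res.Gamma_full.T @ m.Gamma)  # (2 fitted) x (2 true)
        # each true component matched by some fitted component
        assert C.max(axis=0).min() > 0.9

    def test_summary_and_variance_table(self, cap_dataset):
        model = CAPRegression(cap_dataset["A_list"], cap_dataset["design"])
        res = model.fit(R_max=2, seed=0)
        txt = res.summary()
        assert "R selected" in txt and "DfD" in txt
        tab = res.variance_table()
        assert "All" in tab.columns and "Total" in tab.index
        # Total row is the sum of component rows
        np.testing.assert_allclose(
            tab.loc["Total"], tab.drop(index="Total").sum(axis=0), atol=1e-9
        )
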