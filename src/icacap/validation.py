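"""Simulation studies validating the estimators on their generative model.

Each function runs a self-contained numerical experiment — analytic
identity checks, parameter-recovery replicates, bootstrap-coverage
replications, the CAP/pairwise special-case comparison — and returns the
summary quantities.  They are used both by the test suite and by the
repository's acceptance script; problem sizes are chosen to finish on a
single CPU in minutes.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import subspace_angles
from scipy.optimize import linear_sum_assignment

from . import simulate as sim
from .capreg import (
    SampleCovariance,
    dfd,
    fit_component,
    pooled_covariance,
    sample_covariance,
    update_beta,
    update_gamma,
)
from .design import CovariateDesign
from .edgewise import bh_adjust, special_case_check
from .inference import bootstrap_beta, default_contrasts
from .maps import canonicalize_sign
from .reduction import decompose


# ---------------------------------------------------------------------------
# DfD identities
# ---------------------------------------------------------------------------

def dfd_codiagonal(K: int = 4, R: int = 3, n: int = 10, seed: int = 0) -> float:
    """DfD of the true common basis on exactly co-diagonalizable covariances.

    Every subject covariance shares the eigenvectors Q; evaluating DfD on
    R of those columns must give exactly 1.
    """
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((K, K)))
    covs = [
        SampleCovariance(
            (Q * rng.uniform(0.5, 2.0, K)) @ Q.T, T=50, id=f"s{i}"
        )
        for i in range(n)
    ]
    return dfd(Q[:, :R], covs)


def dfd_random_psd_minimum(
    n_ensembles: int = 1000, K: int = 5, R: int = 3, n: int = 5, seed: int = 0
) -> float:
    """Minimum DfD over random PSD ensembles (Hadamard bound check)."""
    rng = np.random.default_rng(seed)
    worst = np.inf
    for _ in range(n_ensembles):
        covs = []
        for i in range(n):
            W = rng.standard_normal((K + 2, K))
            covs.append(SampleCovariance(W.T @ W / (K + 2), T=30, id=f"s{i}"))
        G = rng.standard_normal((K, R))
        worst = min(worst, dfd(G, covs))
    return worst


# ---------------------------------------------------------------------------
# update-step oracles
# ---------------------------------------------------------------------------

def beta_step_oracle_errors() -> dict[str, float]:
    """Deviations of update_beta from its closed-form solutions.

    Intercept-only with responses (1, 3) at equal weight: the optimum is
    the log weighted mean, log 2.  One binary covariate with group
    variances (1, e): intercept 0, slope 1.
    """
    i2 = CovariateDesign(np.ones((2, 1)), ["intercept"])
    covs = [
        SampleCovariance(np.diag([1.0, 5.0]), 10, "a"),
        SampleCovariance(np.diag([3.0, 5.0]), 10, "b"),
    ]
    b0 = update_beta(np.array([1.0, 0.0]), covs, i2)
    err_intercept = abs(b0[0] - np.log(2.0))

    bdes = CovariateDesign(np.array([[1.0, 0.0], [1.0, 1.0]]), ["intercept", "x"])
    covs2 = [
        SampleCovariance(np.diag([1.0, 1.0]), 10, "a"),
        SampleCovariance(np.diag([np.e, 1.0]), 10, "b"),
    ]
    b1 = update_beta(np.array([1.0, 0.0]), covs2, bdes)
    err_slope = float(np.max(np.abs(b1 - np.array([0.0, 1.0]))))
    return {"intercept_error": float(err_intercept), "slope_error": err_slope}


def gamma_step_oracle(seed: int = 0, n_probes: int = 1000) -> dict[str, float]:
    """gamma-step vs the enumerated diagonal solution and random probes.

    On diagonal covariances with identity metric the minimizer of
    gamma' M gamma is the coordinate axis with the smallest diagonal
    entry of M — enumerable by hand.  On random PSD inputs the
    eigen-solution must beat every random feasible unit vector.
    """
    bdes = CovariateDesign(np.array([[1.0, 0.0], [1.0, 1.0]]), ["intercept", "x"])
    covs = [
        SampleCovariance(np.diag([1.0, 1.0]), 10, "a"),
        SampleCovariance(np.diag([np.e, 1.0]), 10, "b"),
    ]
    g = update_gamma(np.array([0.0, 1.0]), covs, bdes, metric=np.eye(2))
    err_diag = float(np.max(np.abs(np.abs(g) - np.array([0.0, 1.0]))))

    rng = np.random.default_rng(seed)
    K, n = 5, 20
    covs_r = []
    for i in range(n):
        W = rng.standard_normal((K + 3, K))
        covs_r.append(SampleCovariance(W.T @ W / (K + 3), 30, f"s{i}"))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    d = CovariateDesign(X, ["intercept", "x"])
    beta = np.array([0.1, 0.4])
    H = pooled_covariance(covs_r)
    g_star = update_gamma(beta, covs_r, d, metric=H)
    Sig = np.stack([c.Sigma_hat for c in covs_r])
    T = np.full(n, 30.0)
    M = np.einsum("i,ijk->jk", T * np.exp(-(X @ beta)), Sig)
    f_star = g_star @ M @ g_star
    beaten = 0
    for _ in range(n_probes):
        v = rng.standard_normal(K)
        v /= np.sqrt(v @ H @ v)
        if f_star <= v @ M @ v + 1e-10:
            beaten += 1
    return {
        "diagonal_error": err_diag,
        "fraction_probes_beaten": beaten / n_probes,
    }


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

#: recovery-study coefficient vector: 0.5 alcohol effect on the common
#: component (intercept, age, gender, alcohol, gender x alcohol)
RECOVERY_BETA = np.array([[0.0], [0.0], [0.0], [0.5], [0.0]])


def recovery_study(
    n_reps: int = 50,
    K: int = 6,
    n: int = 100,
    T: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Replicated single-component fits against the known truth.

    Reports the median |cos angle(gamma_hat, gamma)| and the median
    max-norm coefficient error over replicates.
    """
    counts = (n // 4, n - 3 * (n // 4), n // 4, n // 4)
    cosangles, beta_errs = [], []
    for rep in range(n_reps):
        d = sim.gen_covariates(n, counts, seed=seed + 10 * rep)
        m = sim.gen_true_model(K, 1, RECOVERY_BETA, seed=seed + 10 * rep + 1)
        A = sim.gen_mixing_series(m, d, T, seed=seed + 10 * rep + 2)
        covs = [sample_covariance(a) for a in A]
        comp = fit_component(covs, d, seed=seed + 10 * rep + 3)
        cosangles.append(abs(comp.gamma @ m.Gamma[:, 0]))
        beta_errs.append(float(np.max(np.abs(comp.beta - RECOVERY_BETA[:, 0]))))
    return {
        "median_abs_cos_angle": float(np.median(cosangles)),
        "median_beta_max_error": float(np.median(beta_errs)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# bootstrap coverage
# ---------------------------------------------------------------------------

#: coverage-study truth: non-null gender/alcohol/interaction effects
COVERAGE_BETA = np.array([[0.0], [0.0], [-0.3], [0.5], [0.2]])


def coverage_study(
    n_reps: int = 200,
    B: int = 200,
    alpha: float = 0.05,
    n: int = 100,
    K: int = 6,
    T: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical non-coverage of percentile contrast CIs.

    Data are generated under the model; the true projection is held
    fixed (the bootstrap conditions on the estimated projections in the
    same way) and the four interaction contrasts are checked against
    their known values.
    """
    counts = (n // 4, n - 3 * (n // 4), n // 4, n // 4)
    miss = total = 0
    for rep in range(n_reps):
        d = sim.gen_covariates(n, counts, seed=seed + 10 * rep)
        m = sim.gen_true_model(K, 1, COVERAGE_BETA, seed=seed + 10 * rep + 1)
        gamma = canonicalize_sign(m.Gamma[:, 0])
        A = sim.gen_mixing_series(m, d, T, seed=seed + 10 * rep + 2)
        covs = [sample_covariance(a) for a in A]
        cs = default_contrasts(d)
        true_vals = cs.L @ COVERAGE_BETA[:, 0]
        s = bootstrap_beta(
            covs, d, gamma, B=B, alpha=alpha, seed=seed + 10 * rep + 3,
            contrasts=cs,
        )
        inside = (s.contrast_lower[0] <= true_vals) & (
            true_vals <= s.contrast_upper[0]
        )
        miss += int(np.sum(~inside))
        total += inside.size
    return {
        "non_coverage": miss / total,
        "n_intervals": total,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# BH / FDR
# ---------------------------------------------------------------------------

def bh_oracle_error() -> float:
    """Max deviation from the hand-computed step-up example."""
    q = bh_adjust(np.array([0.005, 0.01, 0.03, 0.04]))
    return float(np.max(np.abs(q - np.array([0.02, 0.02, 0.04, 0.04]))))


def fdp_study(
    n_sims: int = 1000, m: int = 100, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Average false-discovery proportion of BH on uniform nulls."""
    rng = np.random.default_rng(seed)
    fdps = np.empty(n_sims)
    for s in range(n_sims):
        p = rng.uniform(size=m)
        rejected = bh_adjust(p) <= alpha
        nrej = int(rejected.sum())
        fdps[s] = 1.0 if nrej > 0 else 0.0  # all nulls: FDP = V / max(R, 1)
    return {"average_fdp": float(fdps.mean()), "n_sims": n_sims}


# ---------------------------------------------------------------------------
# special-case equivalence
# ---------------------------------------------------------------------------

def special_case_study(
    n_reps: int = 50, n: int = 200, T: int = 500, seed: int = 0
) -> dict[str, float]:
    """CAP-vs-pairwise agreement for small correlation effects.

    Subject pair correlations follow phi_i = exp(x_i' delta) - 1 with
    small delta (|phi| <= ~0.1); the fraction of replicates whose
    largest non-intercept coefficient discrepancy stays below 0.05 is
    reported.
    """
    delta = np.array([0.01, 0.0, 0.03, 0.04, 0.02])
    counts = (n // 4, n - 3 * (n // 4), n // 4, n // 4)
    below = []
    for rep in range(n_reps):
        d = sim.gen_covariates(n, counts, seed=seed + 5 * rep)
        phi = np.exp(d.X @ delta) - 1.0
        rng = np.random.default_rng(seed + 5 * rep + 1)
        A_list = []
        for i in range(n):
            L = np.linalg.cholesky(np.array([[1.0, phi[i]], [phi[i], 1.0]]))
            A_list.append(
                sim.SubjectSeries(id=f"s{i}", M=rng.standard_normal((T, 2)) @ L.T)
            )
        rep_out = special_case_check(A_list, d, (0, 1))
        below.append(rep_out.max_noninter_diff < 0.05)
    return {
        "fraction_within_0p05": float(np.mean(below)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# ICA + dual-regression recovery
# ---------------------------------------------------------------------------

def ica_recovery_study(
    K: int = 5, V: int = 2000, n: int = 8, T: int = 300, seed: int = 0
) -> dict[str, float]:
    """Noise-free recovery of spatial maps and mixing column spaces.

    Reports the smallest Hungarian-matched |correlation| between
    estimated and true maps, and the largest principal angle between
    estimated and true mixing column spaces.
    """
    S = sim.gen_spatial_maps(K, V, sparsity=0.1, seed=seed)
    d = sim.gen_covariates(n, (n // 4, n - 3 * (n // 4), n // 4, n // 4), seed=seed + 1)
    beta = np.array([[0.3], [0.0], [0.0], [0.4], [0.0]])
    m = sim.gen_true_model(K, 1, beta, seed=seed + 2)
    A = sim.gen_mixing_series(m, d, T, seed=seed + 3)
    Y = sim.gen_voxel_data(A, S, noise_sd=0.0)
    dec = decompose(Y, K, seed=seed, standardize=False)
    C = np.abs(np.corrcoef(np.vstack([dec.S, S]))[:K, K:])
    r, c = linear_sum_assignment(-C)
    angles = [
        float(np.max(subspace_angles(a_hat.M, a.M)))
        for a_hat, a in zip(dec.A, A)
    ]
    return {
        "min_matched_map_correlation": float(C[r, c].min()),
        "max_principal_angle": float(max(angles)),
        "ica_converged": bool(dec.meta["ica_converged"]),
    }
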