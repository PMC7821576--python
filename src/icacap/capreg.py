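"""Covariate-assisted principal (CAP) covariance regression.

Given per-subject sample covariances ``Sigma_hat_i`` of K component time
courses and covariates ``x_i``, CAP regression finds unit projections
``gamma`` and coefficients ``beta`` maximizing the Gaussian likelihood of
the projected scores ``z_it = gamma^T a_it`` under the heteroscedastic
log-linear model ``Var(z_it) = exp(x_i^T beta)``.  Up to additive
constants the negative log-likelihood is

    l(gamma, beta) = (1/2) sum_i T_i [ x_i^T beta
                                       + exp(-x_i^T beta) gamma^T Sigma_hat_i gamma ].

Components are extracted sequentially; each gamma-step is a generalized
eigenproblem under the normalization ``gamma^T H gamma = 1`` with H the
pooled weighted covariance, and each beta-step is a Newton-Raphson fit
(a gamma-family GLM with log link in disguise).  Model order R is chosen
from the deviation-from-diagonality (DfD) trace

    DfD(Gamma) = prod_i [ det(diag(Lambda_i)) / det(Lambda_i) ]^{T_i / sum T_i},
    Lambda_i = Gamma^T Sigma_hat_i Gamma,

which equals 1 exactly when Gamma co-diagonalizes every subject
covariance and exceeds 1 otherwise (Hadamard's inequality).

The user-facing surface is statsmodels-like: build a
:class:`CAPRegression` from the mixing series and a design, call
``fit()``, inspect the returned :class:`CAPResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh, null_space

from .design import CovariateDesign
from .simulate import SubjectSeries


class CAPError(RuntimeError):
    """Raised on degenerate inputs or failed optimization."""


class ConvergenceWarningCAP(UserWarning):
    pass


# ---------------------------------------------------------------------------
# covariances
# ---------------------------------------------------------------------------

@dataclass
class SampleCovariance:
    """Sample covariance of one subject's mixing series (divisor T)."""

    Sigma_hat: np.ndarray
    T: int
    id: str = ""

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma_hat, dtype=float)
        if not np.allclose(S, S.T, atol=1e-10):
            raise CAPError(f"covariance of {self.id!r} is not symmetric")
        self.Sigma_hat = 0.5 * (S + S.T)

    @property
    def K(self) -> int:
        return self.Sigma_hat.shape[0]


def sample_covariance(A: SubjectSeries) -> SampleCovariance:
    """Column-centered sample covariance with divisor T (likelihood-consistent)."""
    if A.T < 2:
        raise CAPError(f"series {A.id}: need T >= 2 rows for a covariance")
    M = A.M - A.M.mean(axis=0)
    Sigma = (M.T @ M) / A.T
    return SampleCovariance(Sigma_hat=Sigma, T=A.T, id=A.id)


def _cov_arrays(
    covs: list[SampleCovariance],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack covariances into (n, K, K) with weights (n,)."""
    Sig = np.stack([c.Sigma_hat for c in covs])
    T = np.array([c.T for c in covs], dtype=float)
    return Sig, T


def pooled_covariance(covs: list[SampleCovariance]) -> np.ndarray:
    """Pooled weighted covariance ``H = sum_i T_i Sigma_hat_i / sum_i T_i``."""
    Sig, T = _cov_arrays(covs)
    return np.einsum("i,ijk->jk", T, Sig) / T.sum()


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def neg_log_likelihood(
    gamma: np.ndarray,
    beta: np.ndarray,
    covs: list[SampleCovariance],
    design: CovariateDesign,
) -> float:
    """Negative profile log-likelihood (constants dropped).

    Returns ``(1/2) sum_i T_i [x_i^T beta + exp(-x_i^T beta) s_i]`` with
    ``s_i = gamma^T Sigma_hat_i gamma``.  Overflow in the exponential is
    guarded: the value +inf is returned with a warning.
    """
    Sig, T = _cov_arrays(covs)
    gamma = np.asarray(gamma, dtype=float)
    s = np.einsum("j,ijk,k->i", gamma, Sig, gamma)
    eta = design.X @ np.asarray(beta, dtype=float)
    with np.errstate(over="ignore"):
        val = 0.5 * np.sum(T * (eta + np.exp(-eta) * s))
    if not np.isfinite(val):
        warnings.warn(
            "overflow in exp(-x^T beta); objective is +inf",
            ConvergenceWarningCAP,
        )
        return float("inf")
    return float(val)


def _nll_from_s(
    s: np.ndarray, T: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> float:
    eta = X @ beta
    with np.errstate(over="ignore"):
        v = 0.5 * np.sum(T * (eta + np.exp(-eta) * s))
    return float(v) if np.isfinite(v) else float("inf")


def _newton_beta(
    s: np.ndarray,
    T: np.ndarray,
    X: np.ndarray,
    init: np.ndarray | None,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Newton-Raphson on the convex beta objective, with step halving.

    Gradient (1/2) X^T [T (1 - e^{-eta} s)], Hessian
    (1/2) X^T diag(T e^{-eta} s) X — positive definite whenever s > 0 and
    X has full column rank.
    """
    n, q = X.shape
    if np.linalg.matrix_rank(X) < q:
        raise CAPError("design matrix is rank deficient in beta update")
    if np.any(s <= 0):
        raise CAPError("non-positive projected variance s_i; cannot fit log model")
    if init is None:
        beta = np.zeros(q)
        beta[0] = np.log(np.sum(T * s) / np.sum(T))
    else:
        beta = np.asarray(init, dtype=float).copy()
    obj = _nll_from_s(s, T, X, beta)
    # gradient scales with the total weight; tolerance follows suit
    gtol = tol * max(1.0, T.sum())
    trace = [beta.copy()]
    for _ in range(max_iter):
        eta = X @ beta
        w = np.exp(-eta) * s
        grad = 0.5 * (X.T @ (T * (1.0 - w)))
        if np.linalg.norm(grad) < gtol:
            return beta
        H = 0.5 * (X.T * (T * w)) @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the iteration inside the convex basin; the
        # slack term tolerates rounding when the step is already tiny
        t = 1.0
        for _ in range(60):
            cand = beta - t * step
            cobj = _nll_from_s(s, T, X, cand)
            if cobj <= obj + 1e-12 * max(1.0, abs(obj)):
                break
            t *= 0.5
        beta, obj = cand, cobj
        trace.append(beta.copy())
        if np.linalg.norm(t * step) < 1e-14 * (1.0 + np.linalg.norm(beta)):
            break
    eta = X @ beta
    grad = 0.5 * (X.T @ (T * (1.0 - np.exp(-eta) * s)))
    if np.linalg.norm(grad) < gtol:
        return beta
    raise CAPError(
        f"beta update did not converge in {max_iter} Newton iterations; "
        f"final gradient norm {np.linalg.norm(grad):.3e}; "
        f"iterate trace length {len(trace)}"
    )


def update_beta(
    gamma: np.ndarray,
    covs: list[SampleCovariance],
    design: CovariateDesign,
    init: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Maximize the likelihood in beta for fixed gamma.

    Equivalent to a gamma-family log-link fit of the responses
    ``s_i = gamma^T Sigma_hat_i gamma`` with weights ``T_i``.
    """
    Sig, T = _cov_arrays(covs)
    gamma = np.asarray(gamma, dtype=float)
    s = np.einsum("j,ijk,k->i", gamma, Sig, gamma)
    return _newton_beta(s, T, design.X, init, tol, max_iter)


def update_gamma(
    beta: np.ndarray,
    covs: list[SampleCovariance],
    design: CovariateDesign,
    prev: list[np.ndarray] | None = None,
    metric: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize the likelihood in gamma for fixed beta.

    Solves ``min gamma^T M gamma`` with
    ``M = sum_i T_i exp(-x_i^T beta) Sigma_hat_i`` subject to
    ``gamma^T metric gamma = 1`` and metric-orthogonality to the
    previously extracted components, as a generalized eigenproblem on
    the constraint-complement subspace.
    """
    Sig, T = _cov_arrays(covs)
    K = Sig.shape[1]
    if metric is None:
        metric = pooled_covariance(covs)
    metric = np.asarray(metric, dtype=float)
    prev = prev or []
    if len(prev) >= K:
        raise CAPError("no feasible direction left: R - 1 constraints fill R^K")
    eta = design.X @ np.asarray(beta, dtype=float)
    M = np.einsum("i,ijk->jk", T * np.exp(-eta), Sig)
    if prev:
        P = metric @ np.column_stack(prev)  # constraints gamma^T H gamma_j = 0
        C = null_space(P.T)
    else:
        C = np.eye(K)
    A = C.T @ M @ C
    Bm = C.T @ metric @ C
    vals, vecs = eigh(A, Bm)
    y = vecs[:, 0]  # eigh returns eigenvalues ascending, y^T Bm y = 1
    return C @ y


# ---------------------------------------------------------------------------
# component extraction
# ---------------------------------------------------------------------------

@dataclass
class CAPComponent:
    """One fitted projection: unit-norm gamma, beta, and diagnostics."""

    gamma: np.ndarray
    beta: np.ndarray
    nll: float
    converged: bool
    n_iter: int
    restarts_used: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _canonical_sign(gamma: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude entry is positive (ties: lowest index)."""
    j = int(np.argmax(np.abs(gamma)))
    return -gamma if gamma[j] < 0 else gamma.copy()


def fit_component(
    covs: list[SampleCovariance],
    design: CovariateDesign,
    prev: list[np.ndarray] | None = None,
    n_restarts: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> CAPComponent:
    """Extract one CAP component by alternating beta- and gamma-steps.

    Initializations are the K eigenvectors of the pooled covariance H
    plus random unit vectors up to ``n_restarts`` (default K + 5); the
    best final objective wins.  Both update steps weakly decrease the
    objective, so the per-restart trace is monotone — this is asserted.
    The returned gamma is rescaled to unit Euclidean norm with the
    intercept adjusted by the log of the squared rescaling factor, then
    sign-canonicalized.
    """
    Sig, T = _cov_arrays(covs)
    K = Sig.shape[1]
    if any(c.T <= K for c in covs):
        bad = [c.id for c in covs if c.T <= K]
        raise CAPError(f"need T_i > K={K} for every subject; violated by {bad}")
    prev = list(prev) if prev else []
    if n_restarts is None:
        n_restarts = K + 5
    H = pooled_covariance(covs)
    _, eigvecs = np.linalg.eigh(H)
    rng = np.random.default_rng(seed)
    inits = [eigvecs[:, j] for j in range(K)][:n_restarts]
    while len(inits) < n_restarts:
        v = rng.standard_normal(K)
        inits.append(v / np.linalg.norm(v))

    X = design.X
    best: CAPComponent | None = None
    failures: list[str] = []
    for g0 in inits:
        try:
            # start feasible: project off previous components, H-normalize
            g = g0.copy()
            for p in prev:
                g = g - p * (p @ H @ g) / (p @ H @ p)
            nrm2 = g @ H @ g
            if nrm2 <= 1e-14:
                raise CAPError("initialization collapsed onto constraints")
            g = g / np.sqrt(nrm2)
            beta = None
            obj_prev = np.inf
            trace = []
            converged = False
            it = 0
            for it in range(1, max_iter + 1):
                beta = update_beta(g, covs, design, init=beta)
                g = update_gamma(beta, covs, design, prev=prev, metric=H)
                s = np.einsum("j,ijk,k->i", g, Sig, g)
                obj = _nll_from_s(s, T, X, beta)
                trace.append(obj)
                if obj > obj_prev + 1e-9 * max(1.0, abs(obj_prev)):
                    raise CAPError(
                        f"objective increased ({obj_prev:.10g} -> {obj:.10g})"
                    )
                if abs(obj_prev - obj) <= tol * max(1.0, abs(obj)):
                    converged = True
                    break
                obj_prev = obj
            # final polish of beta at the final gamma
            beta = update_beta(g, covs, design, init=beta)
            s = np.einsum("j,ijk,k->i", g, Sig, g)
            obj = _nll_from_s(s, T, X, beta)
            cand = CAPComponent(
                gamma=g,
                beta=beta,
                nll=obj,
                converged=converged,
                n_iter=it,
                restarts_used=0,
                objective_trace=np.array(trace),
            )
            if best is None or cand.nll < best.nll:
                best = cand
        except CAPError as exc:
            failures.append(str(exc))
            continue
    if best is None:
        raise CAPError(
            "all restarts failed; diagnostics: " + " | ".join(failures[:5])
        )
    best.restarts_used = len(inits) - len(failures)
    # convert to the unit-Euclidean-norm reporting convention
    nrm = np.linalg.norm(best.gamma)
    gamma_unit = best.gamma / nrm
    beta = best.beta.copy()
    # rescaling gamma by c = 1/nrm scales s by c^2; log-scale intercept
    # absorbs log(c^2)
    beta[0] -= np.log(nrm**2)
    best.gamma = _canonical_sign(gamma_unit)
    best.beta = beta
    if not best.converged:
        warnings.warn(
            f"CAP component did not converge in {max_iter} alternations",
            ConvergenceWarningCAP,
        )
    return best


# ---------------------------------------------------------------------------
# model order
# ---------------------------------------------------------------------------

def dfd(Gamma: np.ndarray, covs: list[SampleCovariance]) -> float:
    """Deviation from diagonality of the rotated covariances.

    ``prod_i [det(diag(Lambda_i)) / det(Lambda_i)]^{T_i / sum T_i}`` with
    ``Lambda_i = Gamma^T Sigma_hat_i Gamma``; >= 1 always, = 1 iff all
    rotated matrices are diagonal.  Computed in log space.
    """
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.ndim == 1:
        Gamma = Gamma[:, None]
    if Gamma.ndim != 2 or Gamma.shape[0] < Gamma.shape[1]:
        raise CAPError("Gamma must be a K x R matrix with R <= K")
    Sig, T = _cov_arrays(covs)
    logs = np.empty(len(covs))
    for i, c in enumerate(covs):
        Lam = Gamma.T @ c.Sigma_hat @ Gamma
        sign, logdet = np.linalg.slogdet(Lam)
        d = np.diag(Lam)
        if sign <= 0 or np.any(d <= 0):
            raise CAPError(
                f"rotated covariance of subject {c.id!r} is singular"
            )
        logs[i] = np.sum(np.log(d)) - logdet
    return float(np.exp(np.sum(T * logs) / T.sum()))


def select_R(
    dfd_trace: np.ndarray, tau: float = 2.0, delta: float = 0.5
) -> int:
    """Pick the model order from the DfD trace.

    Returns the largest r (1-based) whose DfD stays below the absolute
    threshold ``tau`` and whose relative jump from r-1 stays below
    ``1 + delta`` (the first entry is compared against 1).  Falls back to
    1 with a warning when no r qualifies.
    """
    t = np.asarray(dfd_trace, dtype=float)
    if t.size == 0:
        raise CAPError("empty DfD trace")
    prev = np.concatenate([[1.0], t[:-1]])
    ok = (t <= tau) & (t / prev <= 1.0 + delta)
    if not ok.any():
        warnings.warn(
            f"no model order satisfies DfD rule (tau={tau}, delta={delta}); "
            "falling back to R=1",
            ConvergenceWarningCAP,
        )
        return 1
    return int(np.nonzero(ok)[0][-1] + 1)


def variance_explained(
    Gamma: np.ndarray, covs: list[SampleCovariance]
) -> np.ndarray:
    """Percent variance each component explains per subject.

    Entry (i, c) is ``100 * gamma_c^T Sigma_hat_i gamma_c / tr(Sigma_hat_i)``;
    gamma columns must be unit Euclidean norm.
    """
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    if Gamma.shape[0] < Gamma.shape[1]:
        Gamma = Gamma.T
    norms = np.linalg.norm(Gamma, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise CAPError("variance_explained expects unit-norm columns")
    Sig, _ = _cov_arrays(covs)
    tr = np.trace(Sig, axis1=1, axis2=2)
    if np.any(tr <= 0):
        raise CAPError("a subject covariance has non-positive trace")
    quad = np.einsum("jc,ijk,kc->ic", Gamma, Sig, Gamma)
    return 100.0 * quad / tr[:, None]


# ---------------------------------------------------------------------------
# sequential fit
# ---------------------------------------------------------------------------

@dataclass
class CAPFitOptions:
    R_max: int = 10
    tau: float = 2.0
    delta: float = 0.5
    n_restarts: int | None = None
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0


def fit_cap(
    covs: list[SampleCovariance],
    design: CovariateDesign,
    R_max: int = 10,
    options: CAPFitOptions | None = None,
) -> "CAPResults":
    """Sequentially extract up to ``R_max`` CAP components and select R.

    Components accumulate metric-orthogonality constraints (H-orthogonal
    to all earlier gammas); after each extraction the DfD of the current
    set is recorded, and ``select_R`` truncates the fit.
    """
    opts = options or CAPFitOptions(R_max=R_max)
    opts.R_max = R_max
    K = covs[0].K
    if R_max > K:
        raise CAPError(f"R_max={R_max} exceeds K={K}")
    H = pooled_covariance(covs)
    components: list[CAPComponent] = []
    prev_metric_scale: list[np.ndarray] = []  # gammas in gamma^T H gamma = 1 scale
    dfd_trace = np.empty(R_max)
    for r in range(R_max):
        comp = fit_component(
            covs,
            design,
            prev=prev_metric_scale,
            n_restarts=opts.n_restarts,
            tol=opts.tol,
            max_iter=opts.max_iter,
            seed=opts.seed + r,
        )
        components.append(comp)
        g = comp.gamma
        prev_metric_scale.append(g / np.sqrt(g @ H @ g))
        Gamma_r = np.column_stack([c.gamma for c in components])
        dfd_trace[r] = dfd(Gamma_r, covs)
    R_sel = select_R(dfd_trace, tau=opts.tau, delta=opts.delta)
    return CAPResults(
        model=None,
        components=components,
        dfd_trace=dfd_trace,
        R_selected=R_sel,
        covs=covs,
        design=design,
        options=opts,
    )


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class CAPRegression:
    """CAP covariance-regression model for multi-subject component series.

    Parameters
    ----------
    A_list : list of SubjectSeries
        Per-subject mixing series (T_i x K), e.g. dual-regressed IC time
        courses.
    design : CovariateDesign
        Covariate design with intercept.

    Examples
    --------
    >>> model = CAPRegression(A_list, design)
    >>> res = model.fit(R_max=6)
    >>> print(res.summary())
    """

    def __init__(self, A_list: list[SubjectSeries], design: CovariateDesign):
        if len(A_list) != design.n:
            raise CAPError(
                f"{len(A_list)} series for {design.n} design rows"
            )
        Ks = {a.n_cols for a in A_list}
        if len(Ks) != 1:
            raise CAPError(f"series disagree on K: {sorted(Ks)}")
        self.A_list = A_list
        self.design = design
        self.K = Ks.pop()
        self.covs = [sample_covariance(a) for a in A_list]

    @classmethod
    def from_arrays(
        cls,
        matrices: list[np.ndarray],
        covariates: pd.DataFrame,
        add_intercept: bool = True,
    ) -> "CAPRegression":
        design = CovariateDesign.from_dataframe(
            covariates, add_intercept=add_intercept
        )
        A_list = [
            SubjectSeries(id=f"sub{i:04d}", M=m) for i, m in enumerate(matrices)
        ]
        return cls(A_list, design)

    def fit(
        self,
        R_max: int | None = None,
        tau: float = 2.0,
        delta: float = 0.5,
        n_restarts: int | None = None,
        tol: float = 1e-8,
        max_iter: int = 500,
        seed: int = 0,
    ) -> "CAPResults":
        if R_max is None:
            R_max = min(self.K, 10)
        opts = CAPFitOptions(
            R_max=R_max,
            tau=tau,
            delta=delta,
            n_restarts=n_restarts,
            tol=tol,
            max_iter=max_iter,
            seed=seed,
        )
        res = fit_cap(self.covs, self.design, R_max=R_max, options=opts)
        res.model = self
        return res


class CAPResults:
    """Fitted CAP regression: projections, coefficients, diagnostics.

    Attributes
    ----------
    Gamma : ndarray (K, R_selected)
        Unit-norm, sign-canonical common projections.
    B : ndarray (q, R_selected)
        Log-linear model coefficients per component.
    dfd_trace : ndarray (R_max,)
        DfD after each sequential extraction.
    R_selected : int
        Model order chosen by the DfD rule.
    """

    def __init__(
        self,
        model: CAPRegression | None,
        components: list[CAPComponent],
        dfd_trace: np.ndarray,
        R_selected: int,
        covs: list[SampleCovariance],
        design: CovariateDesign,
        options: CAPFitOptions,
    ):
        self.model = model
        self.components = components
        self.dfd_trace = dfd_trace
        self.R_selected = R_selected
        self.covs = covs
        self.design = design
        self.options = options

    # full (R_max) and selected-R views ------------------------------------
    @property
    def Gamma_full(self) -> np.ndarray:
        return np.column_stack([c.gamma for c in self.components])

    @property
    def B_full(self) -> np.ndarray:
        return np.column_stack([c.beta for c in self.components])

    @property
    def Gamma(self) -> np.ndarray:
        return self.Gamma_full[:, : self.R_selected]

    @property
    def B(self) -> np.ndarray:
        return self.B_full[:, : self.R_selected]

    @property
    def R_max(self) -> int:
        return len(self.components)

    def var_explained(self) -> np.ndarray:
        """Per-subject percent variance of the selected components."""
        return variance_explained(self.Gamma, self.covs)

    def variance_table(
        self, groups: np.ndarray | None = None, labels: list[str] | None = None
    ) -> pd.DataFrame:
        """Average percent variance per component, overall and by subgroup.

        ``groups`` is an integer label per subject (default: the
        gender x alcohol cell if those columns exist).  A ``Total`` row
        sums the component rows.
        """
        ve = self.var_explained()
        comp_names = [f"C{c + 1}" for c in range(ve.shape[1])]
        table = {"All": ve.mean(axis=0)}
        if groups is None and {"gender", "alcohol"} <= set(self.design.names):
            g = self.design.column("gender").astype(int)
            a = self.design.column("alcohol").astype(int)
            groups = g + 2 * a
            labels = [
                "Female nondrinkers",
                "Male nondrinkers",
                "Female drinkers",
                "Male drinkers",
            ]
        if groups is not None:
            uniq = np.unique(groups)
            if labels is None:
                labels = [f"group{u}" for u in uniq]
            for u, lab in zip(uniq, labels):
                table[lab] = ve[groups == u].mean(axis=0)
        df = pd.DataFrame(table, index=comp_names)
        df.loc["Total"] = df.sum(axis=0)
        return df

    def bootstrap(
        self,
        B: int = 500,
        alpha: float = 0.05,
        seed: int = 0,
        contrasts=None,
        use_selected: bool = True,
    ):
        """Subject-resampling percentile bootstrap for beta and contrasts."""
        from .inference import bootstrap_beta, default_contrasts

        if contrasts is None:
            contrasts = default_contrasts(self.design)
        Gamma = self.Gamma if use_selected else self.Gamma_full
        return bootstrap_beta(
            self.covs,
            self.design,
            Gamma_fixed=Gamma,
            B=B,
            alpha=alpha,
            seed=seed,
            contrasts=contrasts,
        )

    def reconstruct_maps(self, S: np.ndarray, threshold: float = 0.15):
        """CAP brain maps ``Omega = Gamma^T S`` of the selected components."""
        from .maps import reconstruct_maps

        return reconstruct_maps(self.Gamma, S, loading_threshold=threshold)

    def to_dict(self) -> dict:
        return {
            "Gamma": self.Gamma_full.tolist(),
            "B": self.B_full.tolist(),
            "dfd_trace": self.dfd_trace.tolist(),
            "R_selected": self.R_selected,
            "metadata": {
                "seed": self.options.seed,
                "tol": self.options.tol,
                "tau": self.options.tau,
                "delta": self.options.delta,
                "n_iter": [c.n_iter for c in self.components],
                "converged": [bool(c.converged) for c in self.components],
                "gamma_convention": (
                    "columns unit Euclidean norm, sign-canonical; optimization "
                    "used the pooled-covariance metric normalization with the "
                    "intercept corrected on rescale"
                ),
            },
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = []
        lines.append("CAP covariance regression")
        lines.append("=" * 60)
        lines.append(
            f"subjects: {self.design.n}   K: {self.Gamma_full.shape[0]}   "
            f"R_max: {self.R_max}   R selected: {self.R_selected}"
        )
        lines.append(
            "DfD trace: "
            + ", ".join(f"{v:.3f}" for v in self.dfd_trace)
        )
        lines.append("")
        bdf = pd.DataFrame(
            self.B,
            index=self.design.names,
            columns=[f"C{c + 1}" for c in range(self.R_selected)],
        )
        lines.append("log-variance coefficients (beta):")
        lines.append(bdf.round(4).to_string())
        lines.append("")
        lines.append("mean % variance explained per component:")
        ve = self.var_explained().mean(axis=0)
        lines.append(
            "  "
            + "  ".join(
                f"C{c + 1}: {v:.2f}%" for c, v in enumerate(ve)
            )
        )
        return "\n".join(lines)
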