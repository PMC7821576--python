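"""Edge-wise Fisher-z connectivity regression baseline.

The classical analysis of component time courses: Pearson correlation
per component pair, Fisher z-transform, one linear model per edge,
Benjamini-Hochberg FDR across the K(K-1)/2 edges.  Also provides the
special-case check connecting CAP to the pairwise approach: with the
fixed weight vector (1/sqrt(2), 1/sqrt(2)) on a standardized pair the
CAP response is 1 + r, and log(1 + r) approximates the Fisher z of r
for small r, so the two regressions nearly agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .capreg import CAPError, sample_covariance, update_beta
from .design import CovariateDesign
from .inference import ContrastSet
from .simulate import SubjectSeries


def edge_pairs(K: int) -> list[tuple[int, int]]:
    """Unordered pairs (j, k), j < k, in lexicographic order."""
    return [(j, k) for j in range(K) for k in range(j + 1, K)]


def edge_correlations(A: SubjectSeries) -> np.ndarray:
    """Pearson r for every column pair, in ``edge_pairs`` order."""
    if A.T < 3:
        raise CAPError(f"series {A.id}: need T >= 3 for correlations")
    if A.n_cols < 2:
        raise CAPError(f"series {A.id}: need at least 2 columns")
    sd = A.M.std(axis=0)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0].tolist()
        raise CAPError(f"series {A.id}: zero-variance columns {bad}")
    C = np.corrcoef(A.M, rowvar=False)
    iu = np.triu_indices(A.n_cols, k=1)
    return np.clip(C[iu], -1.0, 1.0)


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing transform z = (1/2) log((1+r)/(1-r))."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r_arr)
    return float(out) if np.isscalar(r) else out


def inverse_fisher_z(z) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EdgewiseFit:
    """Mass-univariate OLS of Fisher-z connectivity on covariates.

    Coefficient arrays have shape (P, q); contrast arrays (P, m).
    ``qvals`` are BH-adjusted within each coefficient (column) family
    across the P edges, matching per-contrast displays.
    """

    pairs: list[tuple[int, int]]
    z: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    pvals: np.ndarray
    qvals: np.ndarray
    contrast_labels: list[str]
    contrast_est: np.ndarray
    contrast_se: np.ndarray
    contrast_pvals: np.ndarray
    contrast_qvals: np.ndarray
    design_names: list[str]

    @property
    def P(self) -> int:
        return len(self.pairs)

    @property
    def n_models(self) -> int:
        """Number of separate regressions fitted (the multiplicity burden)."""
        return self.P

    def display_edges(self, alpha: float = 0.05) -> np.ndarray:
        """Mask of edges with any raw contrast p < alpha (plotting rule)."""
        return (self.contrast_pvals < alpha).any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (edge, contrast)."""
        rows = []
        for e, (j, k) in enumerate(self.pairs):
            for m, lab in enumerate(self.contrast_labels):
                rows.append(
                    {
                        "ic_a": j + 1,
                        "ic_b": k + 1,
                        "contrast": lab,
                        "effect": self.contrast_est[e, m],
                        "p": self.contrast_pvals[e, m],
                        "q": self.contrast_qvals[e, m],
                    }
                )
        return pd.DataFrame(rows)


def edgewise_z_matrix(A_list: list[SubjectSeries]) -> np.ndarray:
    """Stack per-subject Fisher-z edge vectors into an n x P matrix."""
    return np.vstack([fisher_z(edge_correlations(a)) for a in A_list])


def fit_edgewise(
    z: np.ndarray,
    design: CovariateDesign,
    contrasts: ContrastSet | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> EdgewiseFit:
    """OLS per edge with t-tests for coefficients and contrasts.

    All edges share the design, so the normal equations are solved once
    (vectorized mass-univariate fit).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, P = z.shape
    X = design.X
    q = design.q
    if n != design.n:
        raise CAPError(f"z has {n} rows for {design.n} subjects")
    if n <= q:
        raise CAPError(f"need n > q, got n={n}, q={q}")
    if np.linalg.matrix_rank(X) < q:
        raise CAPError("design matrix is rank deficient")
    if pairs is None:
        # infer K from P = K(K-1)/2
        K = int(round((1 + np.sqrt(1 + 8 * P)) / 2))
        pairs = edge_pairs(K) if K * (K - 1) // 2 == P else [
            (0, e + 1) for e in range(P)
        ]
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ z  # (q, P)
    resid = z - X @ coef
    dof = n - q
    sigma2 = (resid**2).sum(axis=0) / dof  # (P,)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # (q, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    qvals = np.vstack([bh_adjust(pvals[j]) for j in range(q)])

    if contrasts is None:
        L = np.eye(q)
        labels = list(design.names)
    else:
        L, labels = contrasts.L, list(contrasts.labels)
    c_est = L @ coef  # (m, P)
    c_var = np.einsum("mq,qr,mr->m", L, XtX_inv, L)  # (m,)
    c_se = np.sqrt(np.outer(c_var, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        c_t = np.where(c_se > 0, c_est / c_se, np.inf)
    c_p = 2 * stats.t.sf(np.abs(c_t), dof)
    c_q = np.vstack([bh_adjust(c_p[m]) for m in range(len(labels))])

    return EdgewiseFit(
        pairs=pairs,
        z=z,
        coef=coef.T,
        se=se.T,
        pvals=pvals.T,
        qvals=qvals.T,
        contrast_labels=labels,
        contrast_est=c_est.T,
        contrast_se=c_se.T,
        contrast_pvals=c_p.T,
        contrast_qvals=c_q.T,
        design_names=list(design.names),
    )


@dataclass
class SpecialCaseReport:
    """CAP-vs-pairwise comparison for one edge (fixed equal-weight gamma)."""

    pair: tuple[int, int]
    beta_cap: np.ndarray
    beta_pairwise: np.ndarray
    design_names: list[str]

    @property
    def diff(self) -> np.ndarray:
        return self.beta_cap - self.beta_pairwise

    @property
    def max_noninter_diff(self) -> float:
        """Largest absolute non-intercept coefficient discrepancy."""
        return float(np.max(np.abs(self.diff[1:])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cap": self.beta_cap,
                "pairwise": self.beta_pairwise,
                "diff": self.diff,
            },
            index=self.design_names,
        )


def special_case_check(
    A_list: list[SubjectSeries],
    design: CovariateDesign,
    pair: tuple[int, int] = (0, 1),
) -> SpecialCaseReport:
    """Compare CAP with fixed gamma = (1/sqrt 2, 1/sqrt 2) to Fisher-z OLS.

    Columns of each series are standardized to unit variance first, so
    the CAP response for the pair (j, k) is 1 + r_jk.  For small
    correlations log(1 + r) ~ z(r) and the two coefficient vectors agree
    apart from the intercept.
    """
    j, k = pair
    K = A_list[0].n_cols
    if not (0 <= j < k < K):
        raise CAPError(f"invalid pair {pair} for K={K}")
    std_list = []
    for a in A_list:
        sd = a.M.std(axis=0)
        if np.any(sd == 0):
            raise CAPError(f"series {a.id}: zero-variance column")
        std_list.append(SubjectSeries(id=a.id, M=(a.M - a.M.mean(0)) / sd))
    gamma = np.zeros(K)
    gamma[j] = gamma[k] = 1.0 / np.sqrt(2.0)
    covs = [sample_covariance(a) for a in std_list]
    beta_cap = update_beta(gamma, covs, design)

    r = np.array([np.corrcoef(a.M[:, j], a.M[:, k])[0, 1] for a in std_list])
    z = fisher_z(np.clip(r, -0.999999, 0.999999))
    beta_pw, *_ = np.linalg.lstsq(design.X, z, rcond=None)
    return SpecialCaseReport(
        pair=pair,
        beta_cap=beta_cap,
        beta_pairwise=beta_pw,
        design_names=list(design.names),
    )
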