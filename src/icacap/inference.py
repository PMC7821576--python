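"""Bootstrap inference for CAP coefficients and group contrasts.

Uncertainty is quantified by resampling subjects with replacement:
series (equivalently their sample covariances) and covariate rows are
drawn jointly, the fitted projections are held fixed, and beta is
re-estimated on each resample.  Percentile intervals are read off the
bootstrap distribution.  The same machinery re-estimates beta on
held-out scan sessions with the projections transferred unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capreg import (
    CAPError,
    SampleCovariance,
    _cov_arrays,
    _newton_beta,
    sample_covariance,
)
from .design import CovariateDesign
from .simulate import SubjectSeries


@dataclass
class ContrastSet:
    """Rows of L define linear contrasts ``L beta`` of the coefficients."""

    L: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if len(self.labels) != self.L.shape[0]:
            raise ValueError("one label per contrast row required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("contrast labels must be unique")
        if np.any(np.all(self.L == 0, axis=1)):
            raise ValueError("contrast rows must be nonzero")

    @property
    def m(self) -> int:
        return self.L.shape[0]


def default_contrasts(design: CovariateDesign) -> ContrastSet:
    """The four gender x alcohol interaction contrasts.

    With coefficients (beta_gender, beta_alcohol, beta_interaction):

    1. male vs. female among nondrinkers        -> beta_g
    2. male vs. female among drinkers           -> beta_g + beta_ga
    3. drinkers vs. nondrinkers among females   -> beta_a
    4. drinkers vs. nondrinkers among males     -> beta_a + beta_ga

    Intercept and age carry zero weight in every row.
    """
    needed = ["gender", "alcohol", "gender_x_alcohol"]
    missing = [c for c in needed if c not in design.names]
    if missing:
        raise CAPError(f"design lacks required columns: {missing}")
    jg = design.index_of("gender")
    ja = design.index_of("alcohol")
    jga = design.index_of("gender_x_alcohol")
    L = np.zeros((4, design.q))
    L[0, jg] = 1.0
    L[1, jg] = 1.0
    L[1, jga] = 1.0
    L[2, ja] = 1.0
    L[3, ja] = 1.0
    L[3, jga] = 1.0
    return ContrastSet(
        L=L,
        labels=[
            "male_vs_female_nondrinkers",
            "male_vs_female_drinkers",
            "drinkers_vs_nondrinkers_female",
            "drinkers_vs_nondrinkers_male",
        ],
    )


@dataclass
class BootstrapSummary:
    """Percentile-bootstrap summary per component x contrast (and per beta).

    ``contrast_est`` etc. have shape (R, m) for m contrasts;
    ``beta_est`` has shape (q, R).  ``significant`` flags intervals
    excluding zero.
    """

    contrast_labels: list[str]
    contrast_est: np.ndarray
    contrast_lower: np.ndarray
    contrast_upper: np.ndarray
    beta_est: np.ndarray
    beta_lower: np.ndarray
    beta_upper: np.ndarray
    B: int
    alpha: float
    seed: int
    n_redraws: int = 0
    beta_names: list[str] = field(default_factory=list)
    contrast_draws: np.ndarray | None = None  # (B, R, m), kept for diagnostics

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("need B >= 1 bootstrap replicates")

    @property
    def significant(self) -> np.ndarray:
        """True where the contrast CI excludes zero (shape (R, m))."""
        return (self.contrast_lower > 0) | (self.contrast_upper < 0)

    def to_frame(self) -> pd.DataFrame:
        """Table with one component per row: 'estimate (lower, upper)'."""
        R, m = self.contrast_est.shape
        data = {}
        for j, lab in enumerate(self.contrast_labels):
            data[lab] = [
                f"{self.contrast_est[c, j]:.3f} "
                f"({self.contrast_lower[c, j]:.3f}, {self.contrast_upper[c, j]:.3f})"
                for c in range(R)
            ]
        return pd.DataFrame(data, index=[f"C{c + 1}" for c in range(R)])

    def to_dict(self) -> dict:
        return {
            "contrast_labels": self.contrast_labels,
            "contrast_est": self.contrast_est.tolist(),
            "contrast_lower": self.contrast_lower.tolist(),
            "contrast_upper": self.contrast_upper.tolist(),
            "beta_names": self.beta_names,
            "beta_est": self.beta_est.tolist(),
            "beta_lower": self.beta_lower.tolist(),
            "beta_upper": self.beta_upper.tolist(),
            "significant": self.significant.tolist(),
            "B": self.B,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
        }


def percentile_interval(
    draws: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Order-statistic percentile interval along axis 0.

    The endpoints are the ceil(alpha/2 * B)-th and ceil((1-alpha/2) * B)-th
    order statistics (1-based), so they are always actual bootstrap draws;
    with B=1 both collapse onto the single draw.
    """
    B = draws.shape[0]
    srt = np.sort(draws, axis=0)
    k_lo = max(int(np.ceil(alpha / 2 * B)) - 1, 0)
    k_hi = min(int(np.ceil((1 - alpha / 2) * B)) - 1, B - 1)
    return srt[k_lo], srt[k_hi]


def _as_covs(
    data: list[SampleCovariance] | list[SubjectSeries],
) -> list[SampleCovariance]:
    if data and isinstance(data[0], SubjectSeries):
        return [sample_covariance(a) for a in data]
    return list(data)


def bootstrap_beta(
    A_list: list[SubjectSeries] | list[SampleCovariance],
    design: CovariateDesign,
    Gamma_fixed: np.ndarray,
    B: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    contrasts: ContrastSet | None = None,
    max_redraws: int = 1000,
) -> BootstrapSummary:
    """Percentile bootstrap CIs for beta and contrasts at fixed projections.

    Subjects are resampled with replacement; each fixed column of
    ``Gamma_fixed`` gets its beta re-estimated on the resampled
    covariances.  A resample whose design is rank deficient (e.g. a
    binary covariate constant in the draw) is redrawn and counted.
    Point estimates come from the original sample.
    """
    if B < 1:
        raise CAPError("need B >= 1")
    covs = _as_covs(A_list)
    Gamma = np.asarray(Gamma_fixed, dtype=float)
    if Gamma.ndim == 1:
        Gamma = Gamma[:, None]
    norms = np.linalg.norm(Gamma, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise CAPError("Gamma_fixed columns must be unit norm")
    if contrasts is None:
        contrasts = default_contrasts(design)
    Sig, T = _cov_arrays(covs)
    n = len(covs)
    X = design.X
    R = Gamma.shape[1]
    # projected variances s_{i,c}: bootstrap only reindexes these
    s_all = np.einsum("jc,ijk,kc->ic", Gamma, Sig, Gamma)

    beta_hat = np.column_stack(
        [_newton_beta(s_all[:, c], T, X, None, 1e-10, 100) for c in range(R)]
    )
    rng = np.random.default_rng(seed)
    draws = np.empty((B, design.q, R))
    n_redraws = 0
    for b in range(B):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if np.linalg.matrix_rank(Xb) == design.q:
                break
            n_redraws += 1
        else:
            raise CAPError("could not draw a full-rank bootstrap resample")
        Tb = T[idx]
        for c in range(R):
            draws[b, :, c] = _newton_beta(
                s_all[idx, c], Tb, Xb, beta_hat[:, c], 1e-10, 100
            )
    beta_lo, beta_hi = percentile_interval(draws, alpha)
    # contrasts: (B, q, R) -> (B, R, m)
    cdraws = np.einsum("bqr,mq->brm", draws, contrasts.L)
    c_lo, c_hi = percentile_interval(cdraws, alpha)
    c_est = (contrasts.L @ beta_hat).T  # (R, m)
    if n_redraws:
        warnings.warn(
            f"{n_redraws} rank-deficient bootstrap resamples were redrawn"
        )
    return BootstrapSummary(
        contrast_labels=list(contrasts.labels),
        contrast_est=c_est,
        contrast_lower=c_lo,
        contrast_upper=c_hi,
        beta_est=beta_hat,
        beta_lower=beta_lo,
        beta_upper=beta_hi,
        B=B,
        alpha=alpha,
        seed=seed,
        n_redraws=n_redraws,
        beta_names=list(design.names),
        contrast_draws=cdraws,
    )


def transfer_projection(
    Gamma_fixed: np.ndarray,
    new_session_A_list: list[SubjectSeries],
    design: CovariateDesign,
    B: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    contrasts: ContrastSet | None = None,
    expected_ids: list[str] | None = None,
) -> BootstrapSummary:
    """Re-estimate beta on a held-out session with projections fixed.

    Identical to :func:`bootstrap_beta` except the covariances come from
    the new session's series; ``Gamma_fixed`` is never re-estimated.
    When ``expected_ids`` is given the session's subject ids must match
    it exactly (same subjects, same order as the design).
    """
    if len(new_session_A_list) != design.n:
        raise CAPError(
            f"{len(new_session_A_list)} new-session series for "
            f"{design.n} design rows"
        )
    if expected_ids is not None:
        got = [a.id for a in new_session_A_list]
        if got != list(expected_ids):
            mismatched = [
                (e, g) for e, g in zip(expected_ids, got) if e != g
            ]
            raise CAPError(f"subject id mismatch: {mismatched[:10]}")
    return bootstrap_beta(
        new_session_A_list,
        design,
        Gamma_fixed=Gamma_fixed,
        B=B,
        alpha=alpha,
        seed=seed,
        contrasts=contrasts,
    )
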