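"""Synthetic multi-subject data under the generative connectivity model.

The generator realizes, with known ground truth, the model the rest of
the package estimates:

- voxel series ``Y_i = A_i S (+ noise)`` with shared spatial maps ``S``;
- mixing rows ``a_it ~ N(0, Sigma_i)`` with
  ``Sigma_i = Gamma_i Lambda_i Gamma_i^T``;
- for R shared eigenvectors ``gamma_c`` the eigenvalues follow the
  log-linear model ``log lambda_ic = x_i^T beta_c``; the remaining
  K - R eigenvectors are subject-specific random completions with
  covariate-free eigenvalues.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.stats import ortho_group

from .design import CovariateDesign, DesignError

#: gender x alcohol cell sizes of the reference cohort:
#: (female nondrinkers, male nondrinkers, female drinkers, male drinkers)
DEFAULT_SUBGROUPS = (27, 40, 14, 28)
DEFAULT_AGE_MEAN = 29.0
DEFAULT_AGE_SD = 3.4

#: default range (log scale) of the covariate-free eigenvalues: keeps the
#: common components neither systematically largest nor smallest
DEFAULT_BASE_LOGVAL_RANGE = (np.log(0.5), np.log(2.0))

#: default coefficient templates for q=5 designs
#: (intercept, age, gender, alcohol, gender x alcohol); effect magnitudes
#: around 0.3-0.5 give realistic power at n ~ 110
DEFAULT_BETA = np.array(
    [
        [0.0, 0.2],
        [0.0, 0.0],
        [-0.03, -0.36],
        [0.53, -0.21],
        [-0.44, 0.07],
    ]
)


class SimulationError(ValueError):
    """Raised on inconsistent generator configuration."""


@dataclass
class SubjectSeries:
    """A T x m multivariate time series for one subject.

    ``M`` holds either a mixing series (T x K) or a voxel series (T x V).
    """

    id: str
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2:
            raise SimulationError(f"series {self.id}: matrix must be 2-D")
        if self.M.shape[0] <= 1:
            raise SimulationError(f"series {self.id}: need T > 1 rows")
        if not np.all(np.isfinite(self.M)):
            raise SimulationError(f"series {self.id}: non-finite entries")

    @property
    def T(self) -> int:
        return self.M.shape[0]

    @property
    def n_cols(self) -> int:
        return self.M.shape[1]


@dataclass
class TrueModel:
    """Ground-truth parameters of the generative covariance model.

    Attributes
    ----------
    K : int
        Number of components (dimension of each mixing row).
    R : int
        Number of common, covariate-related components.
    Gamma : ndarray, shape (K, R)
        Orthonormal shared eigenvectors.
    beta : ndarray, shape (q, R)
        Log-linear model coefficients per common component.
    base_logvals : ndarray, shape (K - R,)
        Template log-eigenvalues of the non-common components; per-subject
        values are redrawn from ``base_logval_range`` at series-generation
        time.
    base_logval_range : tuple of float
        (low, high) of the log-uniform law for non-common eigenvalues.
    seed : int
        Seed the model was drawn from.
    """

    K: int
    R: int
    Gamma: np.ndarray
    beta: np.ndarray
    base_logvals: np.ndarray
    seed: int
    base_logval_range: tuple[float, float] = DEFAULT_BASE_LOGVAL_RANGE

    def __post_init__(self) -> None:
        if not (1 <= self.R <= self.K):
            raise SimulationError(f"need 1 <= R <= K, got R={self.R}, K={self.K}")
        G = np.asarray(self.Gamma, dtype=float)
        if G.shape != (self.K, self.R):
            raise SimulationError(f"Gamma must be {self.K}x{self.R}, got {G.shape}")
        if not np.allclose(G.T @ G, np.eye(self.R), atol=1e-10):
            raise SimulationError("Gamma columns are not orthonormal (tol 1e-10)")

    @property
    def q(self) -> int:
        return self.beta.shape[0]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["Gamma"] = self.Gamma.tolist()
        d["beta"] = self.beta.tolist()
        d["base_logvals"] = self.base_logvals.tolist()
        d["base_logval_range"] = list(self.base_logval_range)
        return d


def gen_covariates(
    n: int = 109,
    subgroup_counts: tuple[int, int, int, int] = DEFAULT_SUBGROUPS,
    age_mean: float = DEFAULT_AGE_MEAN,
    age_sd: float = DEFAULT_AGE_SD,
    seed: int = 0,
) -> CovariateDesign:
    """Generate an intercept + age + gender x alcohol covariate design.

    Columns are ``intercept``, ``age`` (Gaussian, centered), ``gender``
    (male = 1), ``alcohol`` (drinker = 1) and their product.  Subgroup
    counts are ordered (female nondrinkers, male nondrinkers,
    female drinkers, male drinkers); the defaults reproduce the
    reference cohort of 109 adults.
    """
    counts = tuple(int(c) for c in subgroup_counts)
    if len(counts) != 4:
        raise SimulationError("subgroup_counts must have 4 entries")
    if sum(counts) != n:
        raise SimulationError(
            f"subgroup counts {counts} sum to {sum(counts)}, expected n={n}"
        )
    if age_sd <= 0:
        raise SimulationError("age_sd must be positive")
    rng = np.random.default_rng(seed)
    fn, mn, fd, md = counts
    gender = np.concatenate(
        [np.zeros(fn), np.ones(mn), np.zeros(fd), np.ones(md)]
    )
    alcohol = np.concatenate(
        [np.zeros(fn + mn), np.ones(fd + md)]
    )
    age = rng.normal(age_mean, age_sd, size=n)
    age = age - age.mean()
    X = np.column_stack(
        [np.ones(n), age, gender, alcohol, gender * alcohol]
    )
    try:
        return CovariateDesign(
            X=X,
            names=["intercept", "age", "gender", "alcohol", "gender_x_alcohol"],
        )
    except DesignError as exc:  # e.g. an all-female cell layout
        raise SimulationError(f"degenerate subgroup layout: {exc}") from exc


def gen_true_model(
    K: int,
    R: int,
    beta: np.ndarray,
    seed: int = 0,
    base_logval_range: tuple[float, float] = DEFAULT_BASE_LOGVAL_RANGE,
) -> TrueModel:
    """Draw ground-truth parameters.

    ``Gamma`` is the first R columns of a Haar-uniform orthogonal K x K
    matrix, so the common subspace has no preferred orientation.
    """
    if not (1 <= R <= K):
        raise SimulationError(f"need 1 <= R <= K, got R={R}, K={K}")
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if beta.shape[1] != R:
        raise SimulationError(f"beta must have R={R} columns, got {beta.shape}")
    rng = np.random.default_rng(seed)
    if K == 1:
        Q = np.array([[rng.choice([-1.0, 1.0])]])
    else:
        Q = ortho_group.rvs(K, random_state=rng)
    lo, hi = base_logval_range
    base_logvals = rng.uniform(lo, hi, size=K - R)
    return TrueModel(
        K=K,
        R=R,
        Gamma=Q[:, :R],
        beta=beta,
        base_logvals=base_logvals,
        seed=seed,
        base_logval_range=(float(lo), float(hi)),
    )


def subject_covariance(
    model: TrueModel, x: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one subject's (Gamma_i, lambda_i, Sigma_i).

    The full eigenvector matrix is ``Gamma_i = [Gamma, U_i]`` with ``U_i``
    a fresh random orthonormal basis of the orthogonal complement of
    ``Gamma``; common eigenvalues are ``exp(x^T beta_c)``, the remaining
    ones log-uniform on ``base_logval_range``.
    """
    K, R = model.K, model.R
    lam = np.empty(K)
    lam[:R] = np.exp(x @ model.beta)
    lo, hi = model.base_logval_range
    lam[R:] = np.exp(rng.uniform(lo, hi, size=K - R))
    if K > R:
        W = rng.standard_normal((K, K - R))
        W -= model.Gamma @ (model.Gamma.T @ W)
        U, _ = np.linalg.qr(W)
        Gamma_i = np.hstack([model.Gamma, U])
    else:
        Gamma_i = model.Gamma
    Sigma = (Gamma_i * lam) @ Gamma_i.T
    return Gamma_i, lam, Sigma


def gen_mixing_series(
    model: TrueModel,
    design: CovariateDesign,
    T: int | list[int],
    seed: int = 0,
) -> list[SubjectSeries]:
    """Generate mixing series ``A_i`` with rows i.i.d. ``N(0, Sigma_i)``."""
    n = design.n
    if np.isscalar(T):
        T_list = [int(T)] * n
    else:
        T_list = [int(t) for t in T]
        if len(T_list) != n:
            raise SimulationError(
                f"{len(T_list)} series lengths for {n} subjects"
            )
    if any(t <= 0 for t in T_list):
        raise SimulationError("all series lengths must be positive")
    if design.q != model.q:
        raise SimulationError(
            f"design has q={design.q} columns, model expects {model.q}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        Gamma_i, lam, _ = subject_covariance(model, design.X[i], rng)
        Z = rng.standard_normal((T_list[i], model.K))
        A = (Z * np.sqrt(lam)) @ Gamma_i.T
        out.append(SubjectSeries(id=f"sub{i:04d}", M=A))
    return out


#: amplitude ratio of background to focal entries in sparse spatial maps
_BACKGROUND_SCALE = 0.05


def gen_spatial_maps(
    K: int, V: int, sparsity: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Generate K independent sparse super-Gaussian spatial maps.

    Entries are Laplace-distributed with a fraction ``sparsity`` of
    large (focal) entries and the rest at a small background amplitude,
    so every voxel stays active while the map is dominated by a sparse
    set of high loadings; rows are scaled to unit Euclidean norm.
    Super-Gaussianity (positive excess kurtosis) is what makes the
    sources recoverable by negentropy-based ICA.
    """
    if V < K:
        raise SimulationError(f"need V >= K, got V={V} < K={K}")
    if not (0 < sparsity <= 1):
        raise SimulationError("sparsity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    S = rng.laplace(0.0, 1.0, size=(K, V))
    if sparsity < 1:
        focal = rng.random(size=(K, V)) < sparsity
        S *= np.where(focal, 1.0, _BACKGROUND_SCALE)
    S /= np.linalg.norm(S, axis=1, keepdims=True)
    return S


def gen_voxel_data(
    A_list: list[SubjectSeries], S: np.ndarray, noise_sd: float = 0.0, seed: int = 0
) -> list[SubjectSeries]:
    """Mix spatial maps into voxel series ``Y_i = A_i S + noise``."""
    S = np.asarray(S, dtype=float)
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for a in A_list:
        if a.n_cols != S.shape[0]:
            raise SimulationError(
                f"series {a.id} has {a.n_cols} components, S has {S.shape[0]} rows"
            )
        Y = a.M @ S
        if noise_sd > 0:
            Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
        out.append(SubjectSeries(id=a.id, M=Y))
    return out
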