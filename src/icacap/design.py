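"""Subject covariate design matrices.

A :class:`CovariateDesign` wraps the n x q design matrix ``X`` whose
first column is the intercept; the log-linear eigenvalue model is
``log lambda_ic = x_i^T beta_c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised when a covariate design violates its invariants."""


@dataclass
class CovariateDesign:
    """An n x q covariate design with an explicit intercept.

    Parameters
    ----------
    X : ndarray, shape (n, q)
        Design matrix.  The first column must be identically one.
    names : list of str
        Column labels, length q.  The first is conventionally
        ``"intercept"``.
    """

    X: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DesignError("design matrix must be 2-D")
        n, q = self.X.shape
        if not self.names:
            self.names = ["intercept"] + [f"x{j}" for j in range(1, q)]
        if len(self.names) != q:
            raise DesignError(f"{len(self.names)} names for {q} columns")
        if not np.all(np.isfinite(self.X)):
            raise DesignError("design matrix contains non-finite entries")
        if not np.all(self.X[:, 0] == 1.0):
            raise DesignError("first design column must be identically 1")
        # n >= q is required for estimation, not for the container itself;
        # fitting routines check rank/sample size where it matters
        # a constant non-intercept column would alias the intercept
        for j in range(1, q):
            if np.ptp(self.X[:, j]) == 0.0:
                raise DesignError(
                    f"column {self.names[j]!r} is constant (aliases intercept)"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return the column labelled ``name``."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise DesignError(f"no column named {name!r}; have {self.names}")
        return self.X[:, j]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DesignError(f"no column named {name!r}; have {self.names}")

    def subset(self, idx: np.ndarray) -> "CovariateDesign":
        """Row-subset (e.g. a bootstrap resample); skips constancy checks."""
        d = object.__new__(CovariateDesign)
        d.X = self.X[idx]
        d.names = list(self.names)
        return d

    def full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.X) == self.q

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, add_intercept: bool = False
    ) -> "CovariateDesign":
        """Build a design from a covariate table.

        With ``add_intercept=True`` a leading column of ones is prepended;
        otherwise the table's first column must already be the intercept.
        """
        X = df.to_numpy(dtype=float)
        names = [str(c) for c in df.columns]
        if add_intercept:
            X = np.column_stack([np.ones(len(df)), X])
            names = ["intercept"] + names
        return cls(X=X, names=names)
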