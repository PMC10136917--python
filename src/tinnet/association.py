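"""Rank correlations feeding network estimation.

Heavily tied 0-3 item responses are correlated with Spearman's rho using
average ranks (the standard tie convention).  Because a matrix of pairwise
rank correlations is not guaranteed positive semidefinite, a deterministic
eigenvalue-clipping repair is provided; the penalised Gaussian likelihood
downstream requires a PSD input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import DegenerateDataError, ItemResponseMatrix

__all__ = [
    "CorrelationMatrix",
    "spearman_matrix",
    "nearest_positive_semidefinite",
    "read_correlation_csv",
    "write_correlation_csv",
]


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with node labels and the sample size behind it."""

    labels: list[str]
    R: np.ndarray
    n: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        p = len(self.labels)
        if self.R.shape != (p, p):
            raise ValueError("R must be square and match labels")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("R must have unit diagonal")
        if np.any(np.abs(self.R) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.labels, columns=self.labels)


def spearman_matrix(responses: ItemResponseMatrix) -> CorrelationMatrix:
    """Pairwise Spearman rho over all items, average ranks for ties.

    A constant item has no rank variance and makes rho undefined; it is
    reported by name in a :class:`DegenerateDataError`.
    """
    X = responses.values
    constant = [
        item for j, item in enumerate(responses.items)
        if np.all(X[:, j] == X[0, j])
    ]
    if constant:
        raise DegenerateDataError(f"constant item(s), rho undefined: {constant}")
    if X.shape[1] == 2:  # spearmanr returns a scalar for two columns
        r = float(stats.spearmanr(X[:, 0], X[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(stats.spearmanr(X).statistic, dtype=float)
    # exact unit diagonal / symmetry regardless of floating noise
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(
        labels=list(responses.items), R=rho, n=responses.n_subjects
    )


def nearest_positive_semidefinite(
    corr: CorrelationMatrix, eig_floor: float = 1e-6
) -> CorrelationMatrix:
    """Clip eigenvalues at ``eig_floor`` and renormalise the diagonal to 1.

    Already-PSD input (smallest eigenvalue >= floor) is returned unchanged.
    The repair is the minimal deterministic perturbation in the eigenbasis,
    followed by the rescaling needed to restore a unit diagonal.
    """
    R = corr.R
    if np.linalg.eigvalsh(R).min() >= eig_floor:
        return corr
    # diagonal renormalisation can push the smallest eigenvalue back under
    # the floor, so clip-and-rescale is iterated to a joint fixed point
    for _ in range(100):
        w, V = np.linalg.eigh(R)
        if w.min() >= eig_floor:
            break
        R = (V * np.clip(w, 1.5 * eig_floor, None)) @ V.T  # headroom for rescale
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(labels=corr.labels, R=R, n=corr.n, method=corr.method)


def write_correlation_csv(corr: CorrelationMatrix, path) -> None:
    """Square labelled CSV, loadable with :func:`read_correlation_csv`."""
    corr.to_frame().to_csv(path, index_label="item")


def read_correlation_csv(path, n: int, method: str = "spearman") -> CorrelationMatrix:
    """Load a square labelled correlation CSV (printed matrices round-trip here).

    ``n`` must be supplied because a printed matrix carries no sample size.
    """
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("correlation CSV must be square with matching labels")
    R = df.to_numpy(dtype=float)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(labels=list(df.columns), R=R, n=n, method=method)
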