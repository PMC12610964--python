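"""PCA-based variable selection.

Variables are standardized (mean 0, sd 1) and the eigendecomposition of
their covariance — equivalently the correlation matrix — yields principal
components.  The smallest set of leading components whose cumulative
explained-variance ratio reaches a threshold (default 0.95) is selected,
and the original variables are ranked by their aggregate loading on the
selected components, weighted by explained variance.  The matrix may be
observations x sensor-variables or variables x features; the caller picks
the orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    """Eigenstructure of the standardized covariance plus the selection.

    ``components[:, k]`` is the loading vector of component ``k`` (columns
    are orthonormal; the entry of largest magnitude is made positive since
    eigenvector sign is arbitrary).  ``contributions[v]`` aggregates
    ``explained_ratio[k] * |loading[v, k]|`` over selected components.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    explained_ratio: np.ndarray
    n_selected: int
    contributions: np.ndarray
    threshold: float
    variables: tuple[str, ...]
    mean_: np.ndarray = field(repr=False, default=None)
    sd_: np.ndarray = field(repr=False, default=None)


def fit_pca(matrix, threshold: float = 0.95,
            variables: list[str] | None = None) -> PCAResult:
    """Standardize, eigendecompose, and select components by threshold.

    ``matrix`` is observations x variables (array or DataFrame).  A
    constant column cannot be standardized; remove it first.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if isinstance(matrix, pd.DataFrame):
        variables = variables or [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    n, p = X.shape if X.ndim == 2 else (0, 0)
    if n < 2 or p < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains missing or non-finite values")
    variables = tuple(variables) if variables else tuple(
        f"V{i + 1}" for i in range(p))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [variables[i] for i in const]
        raise ValueError(f"constant column(s) {names!r} have sd = 0 and "
                         f"cannot be standardized; remove them first")
    Z = (X - mean) / sd
    C = (Z.T @ Z) / (n - 1)          # covariance of standardized data
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # fix arbitrary eigenvector signs: largest-|loading| entry positive
    for k in range(p):
        i = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[i, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    ratio = eigvals / eigvals.sum()
    n_selected = int(np.searchsorted(np.cumsum(ratio), threshold - 1e-12) + 1)
    n_selected = min(n_selected, p)
    contrib = (np.abs(eigvecs[:, :n_selected])
               * ratio[:n_selected]).sum(axis=1)
    return PCAResult(eigenvalues=eigvals, components=eigvecs,
                     explained_ratio=ratio, n_selected=n_selected,
                     contributions=contrib, threshold=threshold,
                     variables=variables, mean_=mean, sd_=sd)


def rank_variable_contributions(result: PCAResult) -> pd.DataFrame:
    """Variables ordered by contribution score, descending.

    Ties keep the original variable order (stable sort).  Returns a
    DataFrame with columns ``variable`` and ``score``.
    """
    order = np.argsort(-result.contributions, kind="stable")
    return pd.DataFrame({
        "variable": [result.variables[i] for i in order],
        "score": result.contributions[order],
    }).reset_index(drop=True)


def explained_variance_table(result: PCAResult) -> pd.DataFrame:
    """Per-component eigenvalue / ratio / cumulative-ratio summary."""
    cum = np.cumsum(result.explained_ratio)
    return pd.DataFrame({
        "component": np.arange(1, result.eigenvalues.size + 1),
        "eigenvalue": result.eigenvalues,
        "explained_ratio": result.explained_ratio,
        "cumulative_ratio": cum,
        "selected": np.arange(result.eigenvalues.size) < result.n_selected,
    })
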