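"""Error metrics and cohort reporting for simulated activity distributions.

For an observed vector ``X`` and a predicted vector ``X_hat`` of length
``N``::

    AAE  = (1/N) * sum_i |X_i - X_hat_i|        (average absolute error)
    AES  = (1/N) * sum_i (X_i - X_hat_i)^2      (average error in squares)
    RMSE = sqrt(AES)

so ``RMSE = sqrt(AES)`` identically and ``AAE <= RMSE`` (the quadratic
mean dominates the arithmetic mean of absolute errors).  The cohort report
pools every per-cow metric value at each iteration count into a single
column mean and an accuracy ``round_half_up(1 - pooled_mean, 2)``, the
layout used for multi-cow simulation studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ErrorReport:
    observed: np.ndarray
    predicted: np.ndarray
    n_components: int
    aae: float
    aes: float
    rmse: float

    def as_dict(self) -> dict[str, float]:
        return {"aae": self.aae, "aes": self.aes, "rmse": self.rmse}


def error_metrics(observed, predicted) -> ErrorReport:
    """AAE / AES / RMSE between two equal-length real vectors."""
    X = np.asarray(observed, dtype=float)
    Xh = np.asarray(predicted, dtype=float)
    if X.shape != Xh.shape or X.ndim != 1:
        raise ValueError(f"observed and predicted must be equal-length "
                         f"vectors, got shapes {X.shape} and {Xh.shape}")
    if X.size < 1:
        raise ValueError("vectors must be non-empty")
    d = X - Xh
    aes = float(np.mean(d * d))
    return ErrorReport(observed=X, predicted=Xh, n_components=X.size,
                       aae=float(np.mean(np.abs(d))), aes=aes,
                       rmse=math.sqrt(aes))


def stationary_similarity(pi_a, pi_b, atol: float = 1e-9) -> ErrorReport:
    """Error metrics between two stationary (probability) distributions.

    Serves as the stationary-similarity measure between a reference
    distribution and, e.g., the empirical frequencies of a simulated chain.
    Both inputs must be normalized (sum to 1 within ``atol``).
    """
    from .markov import StationaryDistribution

    def as_vec(p):
        return p.pi if isinstance(p, StationaryDistribution) else \
            np.asarray(p, dtype=float)

    a, b = as_vec(pi_a), as_vec(pi_b)
    for name, v in (("first", a), ("second", b)):
        if abs(v.sum() - 1.0) > atol:
            raise ValueError(f"{name} distribution sums to {v.sum()!r}, "
                             f"not 1; normalize it first")
    return error_metrics(a, b)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.975 -> 0.98), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortReport:
    """Per-cow error values with pooled column means and accuracies."""

    table: pd.DataFrame                 # tidy: cow, n_iterations, aae, aes, rmse
    pooled_mean: dict[int, float]       # n_iterations -> mean of all values
    accuracy: dict[int, float]          # n_iterations -> 1 - pooled_mean (2 dp)

    def accuracy_percent(self, n_iterations: int) -> float:
        return 100.0 * self.accuracy[n_iterations]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per cow x metric, one column per n, plus
        Average and Accuracy summary rows."""
        wide = self.table.melt(
            id_vars=["cow", "n_iterations"], var_name="metric"
        ).pivot_table(index=["cow", "metric"], columns="n_iterations",
                      values="value", sort=False)
        summary = pd.DataFrame(
            [self.pooled_mean, self.accuracy],
            index=pd.MultiIndex.from_tuples([("Average", ""),
                                             ("Accuracy", "")]))
        summary.columns.name = wide.columns.name
        return pd.concat([wide, summary])


_METRICS = ("aae", "aes", "rmse")


def cohort_table(reports) -> CohortReport:
    """Pool per-cow error reports across iteration counts.

    ``reports`` is either a tidy DataFrame with columns
    ``cow, n_iterations, aae, aes, rmse`` or a nested mapping
    ``{n_iterations: {cow: ErrorReport | (aae, aes, rmse)}}``.  Every
    iteration count must cover the same cow set (ragged input is an error).
    The pooled mean of a column is the arithmetic mean of all
    ``3 * n_cows`` metric values at that iteration count.
    """
    if isinstance(reports, pd.DataFrame):
        tidy = reports.copy()
        missing = [c for c in ("cow", "n_iterations", *_METRICS)
                   if c not in tidy.columns]
        if missing:
            raise ValueError(f"report table missing column(s) {missing!r}")
    else:
        rows = []
        for n, per_cow in reports.items():
            for cow, rep in per_cow.items():
                vals = rep.as_dict() if isinstance(rep, ErrorReport) else \
                    dict(zip(_METRICS, rep))
                rows.append({"cow": cow, "n_iterations": int(n), **vals})
        tidy = pd.DataFrame(rows)
    cow_sets = tidy.groupby("n_iterations")["cow"].apply(
        lambda s: frozenset(s))
    if len(set(cow_sets)) > 1:
        raise ValueError("ragged input: every n_iterations must cover the "
                         "same cow set")
    pooled, accuracy = {}, {}
    for n, grp in tidy.groupby("n_iterations"):
        vals = grp[list(_METRICS)].to_numpy().ravel()
        pooled[int(n)] = float(vals.mean())
        accuracy[int(n)] = round_half_up(1.0 - vals.mean(), 2)
    return CohortReport(table=tidy[["cow", "n_iterations", *_METRICS]],
                        pooled_mean=pooled, accuracy=accuracy)
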