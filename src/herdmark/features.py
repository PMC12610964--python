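"""Per-variable time-series feature extraction.

Eight statistics characterise each sensor variable's series: mean, standard
deviation, curvature, kurtosis, linearity, Shannon entropy, skewness and
trend strength.  High kurtosis flags short intense bursts of activity; high
entropy flags an unpredictable series; trend strength near 1 means the
series is dominated by its smooth component.

Conventions (all configurable where it matters):

* standard deviation: sample (n-1 denominator);
* skewness: bias-corrected sample skewness; kurtosis: excess, bias-corrected;
* Shannon entropy: histogram entropy over ``n_bins`` equal-width bins
  spanning [min, max], natural log, with ``0 log 0 := 0`` — so it lies in
  ``[0, ln(n_bins)]`` and is invariant under positive affine maps;
* trend strength: ``max(0, 1 - Var(remainder) / Var(series))`` from a
  centred moving-average trend decomposition (no seasonal term), in [0, 1];
* linearity / curvature: the degree-1 and degree-2 coefficients of an
  orthogonal-polynomial regression of the trend component on time
  (unbounded; sign carries direction of the trend / bend).

A constant series is assigned sd = entropy = skewness = kurtosis = trend =
linearity = curvature = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FeatureVector:
    mean: float
    sd: float
    curvature: float
    kurtosis: float
    linearity: float
    shannon_entropy: float
    skewness: float
    trend: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES = tuple(f.name for f in fields(FeatureVector))


def _default_window(n: int) -> int:
    """Odd moving-average window, at most 7, shrinking for short series."""
    w = min(7, 2 * (n // 3) + 1)
    return max(3, w if w % 2 == 1 else w - 1)


def _moving_average_trend(x: np.ndarray, window: int) -> np.ndarray:
    # centred MA; partial windows at the edges keep the length unchanged
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def histogram_entropy(x: np.ndarray, n_bins: int = 10) -> float:
    """Shannon entropy (nats) of the equal-width histogram of ``x``."""
    x = np.asarray(x, dtype=float)
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _orthogonal_poly_coeffs(y: np.ndarray) -> tuple[float, float]:
    """Degree-1 and degree-2 coefficients of y on an orthonormal
    polynomial basis of time (QR of the Vandermonde design)."""
    n = y.size
    t = np.linspace(-1.0, 1.0, n)
    X = np.column_stack([np.ones(n), t, t * t])
    Q, _ = np.linalg.qr(X)
    coeffs = Q.T @ y
    return float(coeffs[1]), float(coeffs[2])


def compute_features(series, n_bins: int = 10,
                     window: int | None = None) -> FeatureVector:
    """All eight features of one real-valued series.

    Requires at least 4 finite observations (for the bias-corrected third
    and fourth moments).  Deterministic for fixed input and parameters.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 4:
        raise ValueError(f"series too short ({x.size} < 4)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return FeatureVector(mean=mean, sd=0.0, curvature=0.0, kurtosis=0.0,
                             linearity=0.0, shannon_entropy=0.0,
                             skewness=0.0, trend=0.0)
    w = window if window is not None else _default_window(x.size)
    trend_comp = _moving_average_trend(x, w)
    remainder = x - trend_comp
    var_total = float(np.var(x - x.mean()))
    var_rem = float(np.var(remainder - remainder.mean()))
    trend = max(0.0, 1.0 - var_rem / var_total) if var_total > 0 else 0.0
    linearity, curvature = _orthogonal_poly_coeffs(trend_comp)
    return FeatureVector(
        mean=mean,
        sd=sd,
        curvature=curvature,
        kurtosis=float(stats.kurtosis(x, fisher=True, bias=False)),
        linearity=linearity,
        shannon_entropy=histogram_entropy(x, n_bins),
        skewness=float(stats.skew(x, bias=False)),
        trend=trend,
    )


def build_feature_table(table, n_bins: int = 10,
                        window: int | None = None) -> pd.DataFrame:
    """Feature matrix: one row per sensor variable of an activity table.

    Accepts an :class:`~herdmark.io.ActivityTable` or a DataFrame; any of
    the nine variable columns (T, H, THI, F, M, L, S, RS, RL) that are
    present are featurized.
    """
    from .io import ActivityTable
    from .states import DEFAULT_STATE_SPACE

    frame = table.to_frame() if isinstance(table, ActivityTable) else table
    cols = [c for c in DEFAULT_STATE_SPACE.labels if c in frame.columns]
    if not cols:
        cols = [c for c in frame.columns
                if pd.api.types.is_numeric_dtype(frame[c])]
    if len(frame) < 4:
        raise ValueError("need at least 4 records to featurize")
    rows = {c: compute_features(frame[c].to_numpy(dtype=float),
                                n_bins=n_bins, window=window).as_dict()
            for c in cols}
    return pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]


def plot_feature_profiles(feature_table: pd.DataFrame, ax=None):
    """Grouped-bar chart of selected features across variables.

    Shows the shape/structure features (curvature, kurtosis, linearity,
    entropy, skewness, trend) side by side per variable, the usual visual
    aid when arguing which variables carry consistent temporal structure.
    """
    import matplotlib.pyplot as plt

    show = ["curvature", "kurtosis", "linearity", "shannon_entropy",
            "skewness", "trend"]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    feature_table[show].plot.bar(ax=ax)
    ax.set_ylabel("feature value")
    ax.set_xlabel("variable")
    ax.legend(fontsize=8)
    return ax
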