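"""Pairwise expression correlation with significance.

Thin, strict wrappers around the product-moment and rank correlation:
Pearson r with a two-sided p-value from the t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom, and
Spearman r as Pearson on average ranks.  Missing values are removed pairwise
before ``n`` is counted; degenerate (zero-variance) input raises instead of
propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationResult", "correlate", "correlate_matrix", "bh_fdr"]


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested on a constant vector."""


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation between two features.

    Attributes
    ----------
    feature_a, feature_b : str
        Identifiers of the correlated features.
    r : float
        Correlation coefficient in [-1, 1].
    p : float
        Two-sided p-value.
    n : int
        Number of complete pairs used.
    method : str
        ``"pearson"`` or ``"spearman"``.
    """

    feature_a: str
    feature_b: str
    r: float
    p: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p outside [0, 1]: {self.p}")
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")


def _clean_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    return x, y


def correlate(x, y, method: str = "pearson",
              feature_a: str = "x", feature_b: str = "y") -> CorrelationResult:
    """Correlate two numeric vectors.

    Pairwise deletion of non-finite entries is applied before computing the
    sample size.  ``method`` is ``"pearson"`` or ``"spearman"``; Spearman is
    computed as Pearson on average ranks (ties share their mean rank).

    Raises
    ------
    ZeroVarianceError
        If either vector is constant after deletion (r is undefined).
    """
    x, y = _clean_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(feature_a, feature_b, float(r), float(p),
                             int(x.size), method)


def correlate_matrix(X: np.ndarray, y: np.ndarray, method: str = "pearson"):
    """Correlate every row of ``X`` (features x samples) against ``y``.

    Vectorized equivalent of calling :func:`correlate` per row (no missing
    data handling; rows are assumed complete, as emitted by the simulator).

    Returns
    -------
    (r, p) : pair of arrays, one entry per row of ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 samples")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
        y = stats.rankdata(y)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    # t transform; r == +/-1 maps to p = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
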