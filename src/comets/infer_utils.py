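"""Inference utilities surrounding the covariance measure tests.

Holm step-down familywise-error correction (for batteries of variable or
modality hypotheses), marginal-correlation pre-screening of high-dimensional
feature panels, and SVD reduction of learned embeddings to a tabular block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "holm_adjust", "marginal_screen", "svd_reduce"]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order.

    Sort ascending, multiply the k-th smallest by (m - k + 1), enforce a
    nondecreasing cumulative maximum and cap at 1. Controls the familywise
    error rate without independence assumptions.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class ScreenResult:
    """Outcome of marginal-correlation screening.

    ``selected`` holds indices j with |Cor(Y, X_j)| strictly above the
    threshold; constant columns get correlation 0 and are never selected
    for positive thresholds.
    """

    selected: np.ndarray
    correlations: np.ndarray
    threshold: float


def marginal_screen(Y, X, threshold: float = 0.05) -> ScreenResult:
    """Screen feature columns by absolute marginal Pearson correlation with Y.

    Note that marginal screening is data-driven: feeding its selection into a
    downstream conditional-independence test may inflate false positive
    rates (a caution is logged). The covariance measure tests themselves can
    be run without pre-screening.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    n = Y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for screening")
    if Xm.shape[0] != n:
        raise ValueError("Y and X differ in length")
    yc = Y - Y.mean()
    sy = np.sqrt(np.sum(yc**2))
    Xc = Xm - Xm.mean(axis=0)
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (yc @ Xc) / (sy * sx)
    corr = np.where((sx > 0) & (sy > 0), corr, 0.0)
    selected = np.flatnonzero(np.abs(corr) > threshold)
    logger.warning(
        "marginal screening is data-driven and may lead to inflated false "
        "positive rates in downstream conditional-independence tests"
    )
    return ScreenResult(selected=selected, correlations=corr, threshold=float(threshold))


def svd_reduce(E, variance_target: float = 0.98, max_components: int | None = None):
    """Reduce an embedding matrix to its leading principal-component scores.

    Columns are centered (not scaled); k is the smallest number of components
    whose cumulative squared singular values reach ``variance_target``
    (capped at ``max_components``). Returns ``(scores, k, variance_explained)``
    where scores are the left singular vectors scaled by singular values —
    suitable as a tabular conditioning block for the tests.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] < 1:
        raise ValueError("E must be a matrix with at least one column")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    Ec = E - E.mean(axis=0)
    U, s, _ = np.linalg.svd(Ec, full_matrices=False)
    total = np.sum(s**2)
    if total == 0:
        return np.zeros((E.shape[0], 1)), 1, 1.0
    frac = np.cumsum(s**2) / total
    k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
    k = min(k, s.size)
    if max_components is not None:
        k = min(k, int(max_components))
    scores = U[:, :k] * s[:k]
    return scores, k, float(frac[k - 1])
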