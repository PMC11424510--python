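"""Generalised covariance measure (GCM) test.

The GCM tests conditional independence of a response Y and features X given
Z through the residual products of two regressions: with eps_i the residual
of Y on Z and xi_i the residual of X on Z, the null E[eps * xi] = 0 is
assessed by the standardized statistic

    T = (n^{-1/2} sum_i eps_i xi_i)^2
        / (n^{-1} sum_i eps_i^2 xi_i^2 - (n^{-1} sum_i eps_i xi_i)^2)

which is approximately chi-squared with 1 degree of freedom under the null,
provided the regressions are sufficiently predictive. For d-dimensional X
the per-coordinate products are aggregated either into a quadratic form
(chi-squared with d degrees of freedom) or a max-type statistic calibrated
by a Gaussian multiplier bootstrap.

The GCM targets E[eps * xi], which can be zero under conditional dependence
(e.g. purely quadratic effects of X); the projected covariance measure in
:mod:`comets.pcm` targets a strictly-positive-under-dependence functional
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy import stats

from .regression import (
    RegressorSpec,
    ResidualSet,
    RegressionError,
    residualize,
)

logger = logging.getLogger(__name__)

__all__ = ["GCMResult", "gcm_statistic", "gcm_statistic_multivariate", "gcm_test"]


class DegenerateStatisticError(RuntimeError):
    """Raised when a covariance-measure statistic is undefined on the data."""


@dataclass
class GCMResult:
    """Outcome of a GCM test.

    ``per_coordinate`` holds the standardized mean residual products
    sqrt(n) * mean(R_j) / sd(R_j) per X coordinate; for d = 1 the quadratic
    statistic is exactly the square of that single entry.
    """

    statistic: float
    df: int
    p_value: float
    statistic_type: str
    per_coordinate: np.ndarray
    residual_correlation: Optional[float] = None
    warnings: list[str] = field(default_factory=list)
    spec_yz: Optional[RegressorSpec] = None
    spec_xz: Optional[RegressorSpec] = None
    seed: Optional[int] = None
    n: Optional[int] = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": "gcm",
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "statistic_type": self.statistic_type,
            "per_coordinate": [float(v) for v in np.atleast_1d(self.per_coordinate)],
            "residual_correlation": (
                None if self.residual_correlation is None else float(self.residual_correlation)
            ),
            "warnings": list(self.warnings),
            "spec_yz": None if self.spec_yz is None else self.spec_yz.to_dict(),
            "spec_xz": None if self.spec_xz is None else self.spec_xz.to_dict(),
            "seed": self.seed,
            "n": self.n,
        }


def gcm_statistic(residuals: ResidualSet | None = None, *, eps=None, xi=None) -> tuple[float, float]:
    """Univariate GCM statistic and its chi-squared(1) upper-tail p-value.

    Accepts either a :class:`ResidualSet` or raw ``eps``/``xi`` vectors.
    Raises :class:`DegenerateStatisticError` when the residual products have
    zero variance (the statistic is undefined, not evidence either way).
    """
    if residuals is not None:
        eps, xi = residuals.eps, residuals.other
    eps = np.asarray(eps, dtype=float).ravel()
    xi = np.asarray(xi, dtype=float).ravel()
    if eps.shape[0] != xi.shape[0]:
        raise RegressionError("eps and xi differ in length")
    n = eps.shape[0]
    if n < 2:
        raise RegressionError("need at least 2 observations")
    r = eps * xi
    mean_r = r.mean()
    denom = np.mean(r * r) - mean_r**2
    if denom <= 0:
        raise DegenerateStatisticError("degenerate residual products (zero variance)")
    T = n * mean_r**2 / denom
    return float(T), float(stats.chi2.sf(T, df=1))


def gcm_statistic_multivariate(
    eps: np.ndarray,
    xi_matrix: np.ndarray,
    statistic_type: str = "quadratic",
    n_bootstrap: int = 499,
    seed: int = 0,
) -> tuple[float, dict[str, Any], float]:
    """GCM statistic for d-dimensional X.

    ``quadratic``: with R_i the d-vector of products eps_i * xi_ij,
    T = n * Rbar' Sigma^{-1} Rbar compared to chi-squared(d); a singular
    product covariance falls back to the Moore-Penrose pseudo-inverse with
    the rank as effective degrees of freedom (logged warning).

    ``max``: T = max_j |sqrt(n) Rbar_j| / sd_j, calibrated by a Gaussian
    multiplier bootstrap over the centered products (seeded).

    Returns ``(T, calibration_descriptor, p)``.
    """
    eps = np.asarray(eps, dtype=float).ravel()
    X = np.asarray(xi_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if eps.shape[0] != n:
        raise RegressionError("eps and xi_matrix differ in length")
    R = eps[:, None] * X
    Rbar = R.mean(axis=0)
    Rc = R - Rbar
    if statistic_type == "quadratic":
        if d >= n:
            raise RegressionError(
                "d >= n prohibits the quadratic GCM aggregation; use the max-type "
                "statistic or the PCM test for high-dimensional X"
            )
        Sigma = Rc.T @ Rc / n
        if d == 1:
            # same arithmetic as the univariate form so the reduction is exact
            r = R[:, 0]
            denom = np.mean(r * r) - r.mean() ** 2
            if denom <= 0:
                raise DegenerateStatisticError("degenerate residual products (zero variance)")
            T = float(n * r.mean() ** 2 / denom)
            descriptor = {"calibration": "chi2", "df": 1, "rank_deficient": False}
            return T, descriptor, float(stats.chi2.sf(T, df=1))
        eigvals = np.linalg.eigvalsh(Sigma)
        tol = max(Sigma.shape) * np.finfo(float).eps * max(eigvals.max(), 0.0)
        rank = int(np.sum(eigvals > tol))
        if rank == 0:
            raise DegenerateStatisticError("degenerate residual products (zero variance)")
        rank_deficient = rank < d
        if rank_deficient:
            logger.warning(
                "singular product covariance (rank %d < d=%d); using pseudo-inverse", rank, d
            )
            T = float(n * Rbar @ np.linalg.pinv(Sigma, hermitian=True) @ Rbar)
            df = rank
        else:
            T = float(n * Rbar @ np.linalg.solve(Sigma, Rbar))
            df = d
        descriptor = {"calibration": "chi2", "df": df, "rank_deficient": rank_deficient}
        return T, descriptor, float(stats.chi2.sf(T, df=df))
    if statistic_type == "max":
        sd = Rc.std(axis=0)
        if np.any(sd <= 0):
            raise DegenerateStatisticError("degenerate residual products in some coordinate")
        T = float(np.max(np.abs(np.sqrt(n) * Rbar) / sd))
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((n_bootstrap, n))
        boot = np.max(np.abs(W @ Rc / np.sqrt(n)) / sd, axis=1)
        p = float((1 + np.sum(boot >= T)) / (n_bootstrap + 1))
        descriptor = {
            "calibration": "multiplier_bootstrap",
            "n_bootstrap": n_bootstrap,
            "seed": seed,
        }
        return T, descriptor, p
    raise ValueError(f"unknown statistic_type {statistic_type!r}")


def _empty_z(Z: Optional[np.ndarray], n: int) -> np.ndarray:
    if Z is None:
        return np.empty((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return Z


def gcm_test(
    Y: np.ndarray,
    X: np.ndarray,
    Z: Optional[np.ndarray],
    spec_yz: RegressorSpec,
    spec_xz: RegressorSpec,
    statistic_type: str = "auto",
    residual_mode: str = "in_sample",
    n_folds: int = 5,
    n_bootstrap: int = 499,
    seed: int = 0,
) -> GCMResult:
    """Run the full GCM test of Y independent of X given Z.

    Residualizes Y on Z once and each of the d columns of X on Z (d + 1
    regressions total), then aggregates the residual products. An empty Z
    tests marginal (unconditional) uncorrelatedness: residualization
    degrades to mean-centering. Binary X columns are residualized on the
    probability scale (value minus predicted probability).

    ``statistic_type="auto"`` picks the quadratic form for moderate d
    (d <= min(25, n/10)) and the max-type statistic otherwise.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    n, d = Xm.shape
    Z = _empty_z(Z, n)
    if Y.shape[0] != n or Z.shape[0] != n:
        raise RegressionError("Y, X and Z must have the same number of rows")

    mean_spec = RegressorSpec("mean_only", seed=seed)
    eff_yz = mean_spec if Z.shape[1] == 0 else spec_yz
    eps = residualize(Z, Y, eff_yz, mode=residual_mode, n_folds=n_folds)

    xi = np.empty((n, d))
    for j in range(d):
        col = Xm[:, j]
        if Z.shape[1] == 0:
            spec_j = mean_spec
        else:
            spec_j = spec_xz
            vals = np.unique(col)
            if np.all(np.isin(vals, (0.0, 1.0))) and spec_xz.target_kind != "binary":
                spec_j = spec_xz.replace(target_kind="binary")
        xi[:, j] = residualize(Z, col, spec_j, mode=residual_mode, n_folds=n_folds)

    if statistic_type == "auto":
        statistic_type = "quadratic" if d <= min(25, n / 10) else "max"

    T, descriptor, p = gcm_statistic_multivariate(
        eps, xi, statistic_type=statistic_type, n_bootstrap=n_bootstrap, seed=seed
    )
    Rc = eps[:, None] * xi
    sd = Rc.std(axis=0)
    per_coordinate = np.sqrt(n) * Rc.mean(axis=0) / np.where(sd > 0, sd, np.nan)
    result_warnings = []
    if descriptor.get("rank_deficient"):
        result_warnings.append("singular product covariance; pseudo-inverse used")

    residual_correlation = None
    if d == 1:
        se, sx = eps.std(), xi[:, 0].std()
        if se > 0 and sx > 0:
            residual_correlation = float(np.corrcoef(eps, xi[:, 0])[0, 1])
    return GCMResult(
        statistic=T,
        df=int(descriptor.get("df", d)),
        p_value=p,
        statistic_type=statistic_type,
        per_coordinate=per_coordinate,
        residual_correlation=residual_correlation,
        warnings=result_warnings,
        spec_yz=eff_yz,
        spec_xz=spec_xz,
        seed=seed,
        n=n,
    )
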