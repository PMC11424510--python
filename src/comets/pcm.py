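"""Projected covariance measure (PCM) test.

The PCM targets tau = E[(E[Y|Z] - E[Y|X,Z])^2], which is strictly positive
exactly when X improves mean-squared-error prediction of Y beyond Z. It
works by learning, on one half of the data (D2), a projection direction

    f_hat(x, z) = (g_hat(x, z) - m_hat(z)) / v_hat(x, z)

from three nuisance regressions — g_hat for E[Y|X,Z], m_hat for E[Y|Z] and
v_hat for Var(Y|X,Z) (the regression of squared g_hat-residuals on (X, Z);
the inverse-variance weighting yields a more powerful direction than the
raw difference g_hat - m_hat). On the held-out half (D1) it then forms
response residuals eps_i (Y on Z) and projection residuals zeta_i
(f_hat(X, Z) on Z) and computes the standardized mean product

    T = (n^{-1/2} sum_i eps_i zeta_i)
        / sqrt(n^{-1} sum_i eps_i^2 zeta_i^2 - (n^{-1} sum_i eps_i zeta_i)^2)

rejecting for large T against a standard normal (one-sided, since the
target is nonnegative). Because X only ever enters as a regression *input*,
never as a response, the PCM handles arbitrary high-dimensional or
non-tabular X blocks at a d-independent regression cost.

Sample splitting makes the p-value random; results over K random splits
are aggregated by averaging the statistics and taking the one-sided normal
tail at the average, a conservative but more data-efficient rule than a
single split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy import stats

from .gcm import DegenerateStatisticError
from .regression import FittedRegressor, RegressorSpec, RegressionError, fit_regression, residualize

logger = logging.getLogger(__name__)

__all__ = ["SplitPlan", "ProjectionEstimate", "PCMResult", "make_splits", "fit_projection", "pcm_single_split", "pcm_test"]


@dataclass(frozen=True)
class SplitPlan:
    """A half-sample split: nuisances are fitted on D2, the statistic on D1."""

    indices_d1: np.ndarray
    indices_d2: np.ndarray
    seed: int
    k_index: int

    def validate(self, n: int) -> None:
        d1, d2 = set(self.indices_d1.tolist()), set(self.indices_d2.tolist())
        if d1 & d2:
            raise ValueError("split halves overlap")
        if d1 | d2 != set(range(n)):
            raise ValueError("split halves do not cover all observations")
        if abs(len(d1) - len(d2)) > 1:
            raise ValueError("split halves differ by more than one observation")


def make_splits(n: int, K: int, seed: int) -> list[SplitPlan]:
    """K independent random half-splits of ``range(n)``, seed-deterministic.

    For odd n the extra observation goes to D1 (the statistic half). Fewer
    than 20 observations leave too few per half for nuisance estimation.
    """
    if n < 20:
        raise ValueError("need at least 20 observations for sample splitting")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    n1 = n - n // 2
    plans = []
    for k in range(K):
        perm = rng.permutation(n)
        plans.append(
            SplitPlan(
                indices_d1=np.sort(perm[:n1]),
                indices_d2=np.sort(perm[n1:]),
                seed=seed,
                k_index=k,
            )
        )
    return plans


@dataclass
class ProjectionEstimate:
    """The learned PCM direction f_hat = (g_hat - m_hat) / v_hat.

    The conditional variance enters through a floor: v_hat is clipped below
    at max(``variance_floor_abs``, ``variance_floor_rel`` x median v_hat over
    the evaluation rows) so that a poorly estimated (or nonpositive) variance
    cannot blow up the direction. Clipping is logged and reported.
    """

    g_hat: FittedRegressor
    m_hat: FittedRegressor
    v_hat: FittedRegressor
    variance_floor_abs: float = 1e-6
    variance_floor_rel: float = 0.01
    floor_hits: int = field(default=0, init=False)

    def evaluate(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        XZ = _hstack(X, Z)
        g = self.g_hat.predict(XZ)
        m = self.m_hat.predict(Z)
        v = self.v_hat.predict(XZ)
        med = float(np.median(v))
        floor = max(self.variance_floor_abs, self.variance_floor_rel * med) if med > 0 else self.variance_floor_abs
        clipped = v < floor
        self.floor_hits = int(np.sum(clipped))
        if np.all(v <= 0):
            logger.warning("v_hat nonpositive everywhere; variance floor applies globally")
        elif self.floor_hits:
            logger.warning("variance floor applied to %d evaluation rows", self.floor_hits)
        f = (g - m) / np.maximum(v, floor)
        if not np.all(np.isfinite(f)):
            raise RegressionError("projection produced non-finite values")
        return f


@dataclass
class PCMResult:
    """Outcome of a (multi-split) PCM test."""

    statistic: float
    p_value: float
    per_split: list[dict[str, Any]]
    K: int
    n: int
    seed: int
    specs: dict[str, RegressorSpec]
    warnings: list[str] = field(default_factory=list)
    n_degenerate_splits: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": "pcm",
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "K": int(self.K),
            "n": int(self.n),
            "seed": int(self.seed),
            "per_split": [
                {k: (float(v) if isinstance(v, (int, float, np.floating)) else v) for k, v in rec.items()}
                for rec in self.per_split
            ],
            "specs": {name: spec.to_dict() for name, spec in self.specs.items()},
            "warnings": list(self.warnings),
            "n_degenerate_splits": int(self.n_degenerate_splits),
        }


def _hstack(X: Optional[np.ndarray], Z: Optional[np.ndarray]) -> np.ndarray:
    parts = []
    for M in (X, Z):
        if M is None:
            continue
        M = np.asarray(M, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        if M.shape[1]:
            parts.append(M)
    if not parts:
        raise RegressionError("no feature columns to regress on")
    return np.hstack(parts)


def fit_projection(
    X2: np.ndarray,
    Z2: Optional[np.ndarray],
    Y2: np.ndarray,
    spec_yxz: RegressorSpec,
    spec_yz: RegressorSpec,
    spec_var: Optional[RegressorSpec] = None,
    variance_floor_abs: float = 1e-6,
    variance_floor_rel: float = 0.01,
) -> ProjectionEstimate:
    """Fit the three nuisance regressions of the PCM direction on D2.

    ``spec_var`` defaults to ``mean_only`` (a homoskedastic, constant
    variance estimate — the mean of squared g_hat-residuals); passing a
    flexible spec estimates Var(Y|X,Z) as a function of (X, Z), which is
    what distinguishes the weighted projection from the raw difference.
    """
    Y2 = np.asarray(Y2, dtype=float).ravel()
    n2 = Y2.shape[0]
    Z2m = np.empty((n2, 0)) if Z2 is None else (np.asarray(Z2, float)[:, None] if np.asarray(Z2).ndim == 1 else np.asarray(Z2, float))
    XZ = _hstack(X2, Z2m if Z2m.shape[1] else None)
    if spec_var is None:
        spec_var = RegressorSpec("mean_only", seed=spec_yxz.seed)

    g_hat = fit_regression(XZ, Y2, spec_yxz)
    mean_spec = RegressorSpec("mean_only", seed=spec_yz.seed)
    m_hat = fit_regression(Z2m, Y2, mean_spec if Z2m.shape[1] == 0 else spec_yz)
    sq_resid = (Y2 - g_hat.predict(XZ)) ** 2
    v_hat = fit_regression(XZ, sq_resid, spec_var)
    return ProjectionEstimate(
        g_hat=g_hat,
        m_hat=m_hat,
        v_hat=v_hat,
        variance_floor_abs=variance_floor_abs,
        variance_floor_rel=variance_floor_rel,
    )


def pcm_statistic(eps: np.ndarray, zeta: np.ndarray) -> tuple[float, float, float]:
    """Standardized one-sided statistic from injected residuals.

    Returns ``(T, p, cov_estimate)`` where ``cov_estimate`` is the plug-in
    estimate n^{-1} sum eps_i zeta_i of the projected covariance tau.
    """
    eps = np.asarray(eps, dtype=float).ravel()
    zeta = np.asarray(zeta, dtype=float).ravel()
    if eps.shape[0] != zeta.shape[0]:
        raise RegressionError("eps and zeta differ in length")
    n = eps.shape[0]
    if n < 2:
        raise RegressionError("need at least 2 observations")
    r = eps * zeta
    mean_r = r.mean()
    var_r = np.mean(r * r) - mean_r**2
    if var_r <= 0:
        raise DegenerateStatisticError(
            "f_hat projection residuals degenerate (f_hat may be constant)"
        )
    T = float(np.sqrt(n) * mean_r / np.sqrt(var_r))
    return T, float(stats.norm.sf(T)), float(mean_r)


def pcm_single_split(
    Y1: np.ndarray,
    X1: np.ndarray,
    Z1: Optional[np.ndarray],
    proj: ProjectionEstimate,
    spec_yz: RegressorSpec,
    spec_fz: RegressorSpec,
    residual_mode: str = "in_sample",
) -> tuple[float, float, dict[str, Any]]:
    """Statistic half of one split: residualize on D1 and standardize.

    ``proj`` must be fitted on rows disjoint from D1 (enforced upstream by
    :class:`SplitPlan`). Returns ``(T, cov_estimate, detail)``.
    """
    Y1 = np.asarray(Y1, dtype=float).ravel()
    n1 = Y1.shape[0]
    Z1m = np.empty((n1, 0)) if Z1 is None else (np.asarray(Z1, float)[:, None] if np.asarray(Z1).ndim == 1 else np.asarray(Z1, float))
    mean_spec = RegressorSpec("mean_only", seed=spec_yz.seed)
    eff_yz = mean_spec if Z1m.shape[1] == 0 else spec_yz
    eff_fz = mean_spec if Z1m.shape[1] == 0 else spec_fz

    eps = residualize(Z1m, Y1, eff_yz, mode=residual_mode)
    f_vals = proj.evaluate(X1, Z1m)
    if np.ptp(f_vals) == 0.0:
        raise DegenerateStatisticError(
            "f_hat projection residuals degenerate (f_hat may be constant)"
        )
    zeta = residualize(Z1m, f_vals, eff_fz, mode=residual_mode)
    T, p, cov = pcm_statistic(eps, zeta)
    detail = {"T": T, "p": p, "cov_estimate": cov, "floor_hits": proj.floor_hits, "n1": n1}
    return T, cov, detail


def pcm_test(
    Y: np.ndarray,
    X: np.ndarray,
    Z: Optional[np.ndarray],
    spec_yxz: RegressorSpec,
    spec_yz: RegressorSpec,
    spec_fz: Optional[RegressorSpec] = None,
    spec_var: Optional[RegressorSpec] = None,
    K: int = 5,
    seed: int = 0,
    swap_halves: bool = False,
    residual_mode: str = "in_sample",
) -> PCMResult:
    """Run the PCM test of Y independent of X given Z with K random splits.

    For each split, nuisances (g_hat, m_hat, v_hat) are fitted on D2 and the
    standardized residual-product statistic is computed on D1; the final
    statistic is the mean of the per-split statistics and the p-value the
    one-sided standard-normal tail at that mean (conservative). X never
    appears as a regression response, so it may be any feature block the
    plugged-in learners accept. ``swap_halves=True`` additionally evaluates
    each split with the roles of D1/D2 exchanged (doubling the effective K).
    """
    Y = np.asarray(Y, dtype=float).ravel()
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    n = Y.shape[0]
    Zm = np.empty((n, 0)) if Z is None else (np.asarray(Z, float)[:, None] if np.asarray(Z).ndim == 1 else np.asarray(Z, float))
    if Xm.shape[0] != n or Zm.shape[0] != n:
        raise RegressionError("Y, X and Z must have the same number of rows")
    if spec_fz is None:
        spec_fz = spec_yz

    plans = make_splits(n, K, seed)
    Zopt = Zm if Zm.shape[1] else None
    stats_list: list[float] = []
    per_split: list[dict[str, Any]] = []
    warnings_list: list[str] = []
    n_degenerate = 0
    for plan in plans:
        plan.validate(n)
        role_pairs = [(plan.indices_d1, plan.indices_d2)]
        if swap_halves:
            role_pairs.append((plan.indices_d2, plan.indices_d1))
        for i1, i2 in role_pairs:
            try:
                proj = fit_projection(
                    Xm[i2],
                    None if Zopt is None else Zm[i2],
                    Y[i2],
                    spec_yxz=spec_yxz,
                    spec_yz=spec_yz,
                    spec_var=spec_var,
                )
                T, cov, detail = pcm_single_split(
                    Y[i1],
                    Xm[i1],
                    None if Zopt is None else Zm[i1],
                    proj,
                    spec_yz=spec_yz,
                    spec_fz=spec_fz,
                    residual_mode=residual_mode,
                )
            except DegenerateStatisticError as exc:
                n_degenerate += 1
                per_split.append({"k": plan.k_index, "degenerate": str(exc)})
                continue
            detail["k"] = plan.k_index
            stats_list.append(T)
            per_split.append(detail)
            if detail["floor_hits"]:
                warnings_list.append(
                    f"variance floor applied on split {plan.k_index} ({detail['floor_hits']} rows)"
                )
    if not stats_list:
        raise DegenerateStatisticError("all splits degenerate; PCM statistic undefined")
    T_bar = float(np.mean(stats_list))
    p = float(stats.norm.sf(T_bar))
    return PCMResult(
        statistic=T_bar,
        p_value=p,
        per_split=per_split,
        K=K,
        n=n,
        seed=seed,
        specs={
            "yxz": spec_yxz,
            "yz": spec_yz,
            "fz": spec_fz,
            "var": spec_var if spec_var is not None else RegressorSpec("mean_only", seed=spec_yxz.seed),
        },
        warnings=warnings_list,
        n_degenerate_splits=n_degenerate,
    )
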