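"""Seeded synthetic data-generating processes with analytic oracles.

Every DGP needed to exercise the covariance measure tests without external
data lives here, each with the statistical structure that motivates one of
the tests:

``fig2_product``
    Y = (1 + sin(3 X^2)) (1 + Z^3) + noise with X, Z iid standard normal.
    The population X-on-Z residual is X itself and E[eps * X] = 0 by odd
    symmetry, so the GCM is blind to this alternative, while the projected
    covariance tau = Var(f(X)) E[g(Z)^2] is strictly positive — the PCM's
    home turf.
``quadratic_blind``
    Y = X^2 (+ optional noise), X and Z independent standard normal. Here
    E[Y|Z] = 1, eps = Y - 1, xi = X and E[eps xi] = E[(X^2 - 1) X] = 0: a
    conditionally dependent pair the GCM cannot detect even in population.
``partially_linear``
    E[Y|X,Z] = theta X + h(Z) with h a fixed smooth nonlinearity and X
    linearly confounded with Z. The GCM's target is proportional to theta;
    theta = 0 gives an exact null with an exactly linear E[X|Z].
``pure_null``
    Y depends on Z only (linearly), X is linearly dependent on Z: a null
    where linear learners are correctly specified for every regression.
``block_multimodal``
    Three correlated feature blocks with a binary event response driven by
    one block — the shape of a multiomics modality-selection problem.
``binary_panel``
    Sparse 0/1 feature columns with the response driven by a small subset —
    the shape of a mutation-panel variable-significance problem.

DGPs with closed-form conditional means expose an :class:`Oracle` with the
exact population residuals, so calibration can be checked independently of
learner quality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Optional

import numpy as np

__all__ = ["DGPConfig", "Oracle", "SimulatedDataset", "generate", "oracle_gcm_covariance"]

_DGP_NAMES = (
    "fig2_product",
    "quadratic_blind",
    "partially_linear",
    "pure_null",
    "block_multimodal",
    "binary_panel",
)

# per-DGP default noise standard deviations (used when noise_sd is None)
_DEFAULT_NOISE = {
    "fig2_product": 0.5,
    "quadratic_blind": 0.0,
    "partially_linear": 1.0,
    "pure_null": 1.0,
    "block_multimodal": 0.0,
    "binary_panel": 1.0,
}

# E[sin(3 X^2)] for X ~ N(0,1), from the chi-squared(1) characteristic
# function E[exp(i t X^2)] = (1 - 2 i t)^{-1/2} at t = 3.
_E_SIN_3X2 = float(((1 - 6j) ** -0.5).imag)


@dataclass(frozen=True)
class DGPConfig:
    """Declarative configuration of a synthetic data-generating process."""

    dgp_name: str
    n: int
    theta: float = 0.0
    noise_sd: Optional[float] = None
    d_x: int = 1
    d_z: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dgp_name not in _DGP_NAMES:
            raise ValueError(f"unknown dgp_name {self.dgp_name!r}; known: {_DGP_NAMES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def sigma(self) -> float:
        return _DEFAULT_NOISE[self.dgp_name] if self.noise_sd is None else float(self.noise_sd)

    def to_dict(self) -> dict[str, Any]:
        return {
            "dgp_name": self.dgp_name,
            "n": self.n,
            "theta": self.theta,
            "noise_sd": self.sigma,
            "d_x": self.d_x,
            "d_z": self.d_z,
            "seed": self.seed,
        }


@dataclass
class Oracle:
    """Exact population conditional means/variance evaluated on the sample.

    ``eps`` and ``xi`` are the population residuals Y - E[Y|Z] and
    X - E[X|Z]; no estimation is involved.
    """

    mean_yxz: np.ndarray
    mean_yz: np.ndarray
    mean_xz: Optional[np.ndarray]
    var_yxz: np.ndarray
    eps: np.ndarray
    xi: Optional[np.ndarray]


@dataclass
class SimulatedDataset:
    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    truth: str  # "null_holds" or "alternative"
    config: DGPConfig
    oracle: Optional[Oracle] = None
    blocks: Optional[dict[str, slice]] = None


def _fig2_f(x: np.ndarray) -> np.ndarray:
    return 1.0 + np.sin(3.0 * x**2)


def _fig2_g(z: np.ndarray) -> np.ndarray:
    return 1.0 + z**3


def _weights(d: int) -> np.ndarray:
    return np.ones(d) / np.sqrt(d)


def generate(config: DGPConfig) -> SimulatedDataset:
    """Draw a seeded dataset from the configured DGP (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n, sigma = config.n, config.sigma
    name = config.dgp_name

    if name == "fig2_product":
        X = rng.standard_normal(n)
        Z = rng.standard_normal(n)
        noise = sigma * rng.standard_normal(n)
        Y = _fig2_f(X) * _fig2_g(Z) + noise
        mean_yxz = _fig2_f(X) * _fig2_g(Z)
        mean_yz = (1.0 + _E_SIN_3X2) * _fig2_g(Z)
        oracle = Oracle(
            mean_yxz=mean_yxz,
            mean_yz=mean_yz,
            mean_xz=np.zeros((n, 1)),
            var_yxz=np.full(n, sigma**2),
            eps=Y - mean_yz,
            xi=X[:, None],
        )
        return SimulatedDataset(Y, X[:, None], Z[:, None], "alternative", config, oracle)

    if name == "quadratic_blind":
        X = rng.standard_normal(n)
        Z = rng.standard_normal((n, config.d_z))
        Y = X**2 + sigma * rng.standard_normal(n)
        oracle = Oracle(
            mean_yxz=X**2,
            mean_yz=np.ones(n),
            mean_xz=np.zeros((n, 1)),
            var_yxz=np.full(n, sigma**2),
            eps=Y - 1.0,
            xi=X[:, None],
        )
        return SimulatedDataset(Y, X[:, None], Z, "alternative", config, oracle)

    if name == "partially_linear":
        Z = rng.standard_normal((n, config.d_z))
        w = _weights(config.d_z)
        gamma = 0.5 * w
        mean_xz = Z @ gamma
        X = mean_xz + rng.standard_normal(n)
        h = np.cos(2.0 * (Z @ w))
        Y = config.theta * X + h + sigma * rng.standard_normal(n)
        mean_yxz = config.theta * X + h
        mean_yz = config.theta * mean_xz + h
        oracle = Oracle(
            mean_yxz=mean_yxz,
            mean_yz=mean_yz,
            mean_xz=mean_xz[:, None],
            var_yxz=np.full(n, sigma**2),
            eps=Y - mean_yz,
            xi=(X - mean_xz)[:, None],
        )
        truth = "null_holds" if config.theta == 0.0 else "alternative"
        return SimulatedDataset(Y, X[:, None], Z, truth, config, oracle)

    if name == "pure_null":
        Z = rng.standard_normal((n, config.d_z))
        w = _weights(config.d_z)
        mean_yz = Z @ w
        Y = mean_yz + sigma * rng.standard_normal(n)
        mean_xz = np.tile((0.5 * (Z @ w))[:, None], (1, config.d_x))
        X = mean_xz + rng.standard_normal((n, config.d_x))
        oracle = Oracle(
            mean_yxz=mean_yz.copy(),
            mean_yz=mean_yz,
            mean_xz=mean_xz,
            var_yxz=np.full(n, sigma**2),
            eps=Y - mean_yz,
            xi=X - mean_xz,
        )
        return SimulatedDataset(Y, X, Z, "null_holds", config, oracle)

    if name == "block_multimodal":
        b = config.d_x  # per-block dimension
        latent = rng.standard_normal((n, 2))
        blocks, names = [], ("block1", "block2", "block3")
        loadings = rng.standard_normal((3, 2, b)) * 0.7
        for k in range(3):
            blocks.append(latent @ loadings[k] + rng.standard_normal((n, b)))
        Xall = np.hstack(blocks)
        w = _weights(b) * 1.5
        eta = blocks[2] @ w
        prob = 1.0 / (1.0 + np.exp(-eta))
        Y = (rng.random(n) < prob).astype(float)
        slices = {names[k]: slice(k * b, (k + 1) * b) for k in range(3)}
        return SimulatedDataset(Y, Xall, np.empty((n, 0)), "alternative", config, blocks=slices)

    if name == "binary_panel":
        d = config.d_x
        freqs = rng.uniform(0.05, 0.3, size=d)
        X = (rng.random((n, d)) < freqs).astype(float)
        beta = np.zeros(d)
        k = min(3, d)
        beta[:k] = np.array([1.0, 0.8, 0.6])[:k]
        Y = X @ beta + sigma * rng.standard_normal(n)
        return SimulatedDataset(Y, X, np.empty((n, 0)), "alternative", config)

    raise ValueError(f"unknown dgp_name {name!r}")  # pragma: no cover


def oracle_gcm_covariance(
    config: DGPConfig, n_mc: int, seed: Optional[int] = None
) -> tuple[float, float]:
    """Monte-Carlo estimate of E[eps * xi] using exact oracle residuals.

    Returns ``(estimate, standard_error)``. Only defined for DGPs with an
    analytic oracle channel; the estimate targets the population residual
    covariance the GCM tests for (zero under the null, and zero for the
    GCM-blind alternatives by construction).
    """
    cfg = replace(config, n=n_mc, seed=config.seed if seed is None else seed)
    ds = generate(cfg)
    if ds.oracle is None or ds.oracle.xi is None:
        raise ValueError(f"DGP {config.dgp_name!r} has no analytic oracle residuals")
    r = ds.oracle.eps * ds.oracle.xi[:, 0]
    est = float(r.mean())
    se = float(r.std(ddof=1) / np.sqrt(n_mc))
    return est, se
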