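"""Cell-line-specific network estimation via a varying-coefficient model.

For each cell line ``alpha`` with drug-sensitivity value ``m_alpha``, every
gene in turn is regressed on all other genes under Gaussian-kernel weights

    K(m_i - m_alpha | b) = exp(-(m_i - m_alpha)^2 / b),

so that cell lines with sensitivity similar to ``m_alpha`` dominate the fit,
and the coefficients are penalised with a recursive (adaptive) elastic net:

    1/2 sum_i K_i (y_il - beta' x_i)^2
        + lam * sum_j [ 1/2 (1-delta) beta_j^2 + delta w_j |beta_j| ].

The adaptive weights ``w_j`` start at 1 and are refreshed from the previous
fit as ``1 / (|beta_j| + eps)``, which de-biases retained edges and prunes
noise edges.  The result is one directed coefficient matrix per cell line
(rows = targets, columns = regulators, zero diagonal) that varies smoothly
with the sensitivity value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import enet_path
from .containers import ExpressionMatrix, SensitivityProfile, align

__all__ = [
    "EstimatorConfig",
    "VaryingCoefficientNetwork",
    "gaussian_kernel",
    "select_bandwidth",
    "fit_target_model",
    "estimate_all_networks",
    "networks_to_long_frame",
]

#: Hard ceiling for the automatic bandwidth search, as a multiple of the
#: squared spread of the sensitivity values.
_BANDWIDTH_CAP_FACTOR = 1e6


def gaussian_kernel(m_i, m_alpha, bandwidth: float):
    """Gaussian kernel weight ``exp(-(m_i - m_alpha)^2 / bandwidth)``.

    Symmetric in its first two arguments; value in ``(0, 1]``.  Accepts
    scalars or arrays broadcast against each other.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    d = np.asarray(m_i, dtype=float) - np.asarray(m_alpha, dtype=float)
    out = np.exp(-(d * d) / bandwidth)
    if out.ndim == 0:
        return float(out)
    return out


def _mean_ess(m: np.ndarray, bandwidth: float) -> float:
    d2 = (m[:, None] - m[None, :]) ** 2
    return float(np.exp(-d2 / bandwidth).sum(axis=0).mean())


def select_bandwidth(
    profile: SensitivityProfile,
    rule: str = "ess-fraction",
    fraction: float = 1.0 / 3.0,
    b_max: float | None = None,
) -> float:
    """Choose the kernel bandwidth from the sensitivity values alone.

    The default (and only) rule solves, by bisection, for the bandwidth at
    which the mean effective sample size ``mean_alpha sum_i K(m_i - m_alpha)``
    equals ``fraction * n``.  A demanded fraction at or above 1 is attainable
    only in the infinite-bandwidth limit; the search is then capped and a
    warning issued.
    """
    if rule != "ess-fraction":
        raise ValueError(f"unknown bandwidth rule: {rule!r}")
    m = np.asarray(profile.values, dtype=float)
    if np.unique(m).size < 3:
        raise ValueError("bandwidth selection needs at least 3 distinct sensitivity values")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = m.size
    spread = float(m.max() - m.min())
    cap = b_max if b_max is not None else _BANDWIDTH_CAP_FACTOR * spread**2
    target = fraction * n
    if _mean_ess(m, cap) <= target:
        warnings.warn(
            "requested effective sample size is only reached in the "
            "infinite-bandwidth limit; returning the capped maximum",
            RuntimeWarning,
            stacklevel=2,
        )
        return cap
    lo = 1e-12 * spread**2
    hi = cap
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisect in log space
        if _mean_ess(m, mid) < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    return float(np.sqrt(lo * hi))


@dataclass(frozen=True)
class EstimatorConfig:
    """Tuning parameters of the kernel-weighted recursive elastic net.

    ``bandwidth="auto"`` triggers :func:`select_bandwidth` with
    ``ess_fraction``.  ``lambda_grid=None`` builds, per fit, a geometric grid
    of ``n_lambda`` values from the KKT threshold ``lambda_max`` down to
    ``lambda_max * lambda_min_ratio``.
    """

    bandwidth: float | str = "auto"
    ess_fraction: float = 1.0 / 3.0
    lambda_grid: tuple[float, ...] | None = None
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-3
    delta: float = 0.5
    adaptive_iterations: int = 2
    adaptive_epsilon: float = 1e-6
    selection_rule: str = "weighted-bic"  # or "weighted-cv"
    n_cv_folds: int = 5
    standardize: bool = True
    tol: float = 1e-8
    max_sweeps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie strictly in (0, 1)")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "auto":
                raise ValueError(f"bandwidth must be positive or 'auto', got {self.bandwidth!r}")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.lambda_grid is not None and len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be nonempty")
        if self.adaptive_iterations < 1:
            raise ValueError("adaptive_iterations must be >= 1")
        if self.adaptive_epsilon <= 0:
            raise ValueError("adaptive_epsilon must be positive")
        if self.selection_rule not in ("weighted-bic", "weighted-cv"):
            raise ValueError(f"unknown selection rule: {self.selection_rule!r}")


@dataclass
class VaryingCoefficientNetwork:
    """Directed network for one cell line: entry ``(l, j)`` is the effect of
    regulator ``j`` on target ``l`` at that cell line's sensitivity value."""

    coefficients: np.ndarray  # (p, p), zero diagonal
    cell_line_id: str
    m_value: float
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        p = len(self.gene_ids)
        if self.coefficients.shape != (p, p):
            raise ValueError("coefficient matrix shape does not match gene ids")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficient matrix contains non-finite entries")
        if np.any(np.diag(self.coefficients) != 0):
            raise ValueError("self-regulation (diagonal) must be zero")


def _standardized(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd_safe


def _resolve_bandwidth(profile: SensitivityProfile, config: EstimatorConfig) -> float:
    if config.bandwidth == "auto":
        return select_bandwidth(profile, fraction=config.ess_fraction)
    return float(config.bandwidth)


def _lambda_grid(c: np.ndarray, w: np.ndarray, config: EstimatorConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        return np.sort(np.asarray(config.lambda_grid, dtype=float))[::-1]
    lam_max = float(np.max(np.abs(c) / (config.delta * w))) if c.size else 0.0
    if lam_max <= 0:
        return np.array([1.0])  # response orthogonal to all regressors; any grid gives 0
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def _weighted_bic(
    betas: np.ndarray, G: np.ndarray, c: np.ndarray, yKy: float, n_eff: float
) -> np.ndarray:
    rss = yKy - 2.0 * betas @ c + np.einsum("lj,jk,lk->l", betas, G, betas)
    rss = np.maximum(rss, 1e-12)
    df = (betas != 0).sum(axis=1)
    return n_eff * np.log(rss / n_eff) + np.log(n_eff) * df


def _fit_coefficients(
    Xs: np.ndarray,
    y: np.ndarray,
    K: np.ndarray,
    config: EstimatorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Adaptive elastic-net fit of one target on regressors ``Xs``."""
    Kx = Xs * K[:, None]
    G = Xs.T @ Kx
    c = Kx.T @ y
    yKy = float(y @ (K * y))
    n_eff = float(K.sum())
    w = np.ones(Xs.shape[1])
    beta = np.zeros(Xs.shape[1])
    for _ in range(config.adaptive_iterations):
        grid = _lambda_grid(c, w, config)
        betas = enet_path(G, c, grid, config.delta, w, config.tol, config.max_sweeps)
        if config.selection_rule == "weighted-bic":
            crit = _weighted_bic(betas, G, c, yKy, n_eff)
        else:
            crit = _cv_criterion(Xs, y, K, grid, w, config, rng)
        beta = betas[int(np.argmin(crit))]
        w = 1.0 / (np.abs(beta) + config.adaptive_epsilon)
    return beta


def _cv_criterion(
    Xs: np.ndarray,
    y: np.ndarray,
    K: np.ndarray,
    grid: np.ndarray,
    w: np.ndarray,
    config: EstimatorConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Kernel-weighted cross-validation error for each lambda in ``grid``."""
    n = y.size
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, config.n_cv_folds)
    err = np.zeros(grid.size)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Kt = K[mask]
        Xt, yt = Xs[mask], y[mask]
        Gt = Xt.T @ (Xt * Kt[:, None])
        ct = (Xt * Kt[:, None]).T @ yt
        betas = enet_path(Gt, ct, grid, config.delta, w, config.tol, config.max_sweeps)
        resid = y[fold][None, :] - betas @ Xs[fold].T
        err += (K[fold][None, :] * resid**2).sum(axis=1)
    return err


def fit_target_model(
    expr: ExpressionMatrix,
    target_index: int,
    m_alpha: float,
    profile: SensitivityProfile,
    config: EstimatorConfig = EstimatorConfig(),
) -> np.ndarray:
    """Coefficient vector of one target gene at sensitivity value ``m_alpha``.

    Returns a length-``p`` vector aligned with ``expr.gene_ids``; the entry
    for the target itself is structurally zero (no self-regulation).
    """
    expr, profile, _ = align(expr, profile)
    p = expr.n_genes
    if not 0 <= target_index < p:
        raise IndexError(f"target index {target_index} out of range for {p} genes")
    X = _standardized(expr.values) if config.standardize else expr.values
    b = _resolve_bandwidth(profile, config)
    K = gaussian_kernel(profile.values, m_alpha, b)
    if K.sum() <= 0:
        raise ValueError("all kernel weights underflowed to zero; increase the bandwidth")
    others = np.arange(p) != target_index
    beta = np.zeros(p)
    beta[others] = _fit_coefficients(X[:, others], X[:, target_index], K, config)
    return beta


def estimate_all_networks(
    expr: ExpressionMatrix,
    profile: SensitivityProfile,
    config: EstimatorConfig = EstimatorConfig(),
    at_cell_lines: list[str] | None = None,
) -> list[VaryingCoefficientNetwork]:
    """One varying-coefficient network per cell line.

    Each network is estimated at that cell line's sensitivity value; targets
    are fitted independently, so the result does not depend on evaluation
    order.  ``at_cell_lines`` restricts which cell lines get a network while
    all cell lines still contribute kernel-weighted observations.
    """
    expr, profile, _ = align(expr, profile)
    n, p = expr.values.shape
    X = _standardized(expr.values) if config.standardize else expr.values
    b = _resolve_bandwidth(profile, config)
    m = profile.values
    wanted = expr.cell_line_ids if at_cell_lines is None else list(at_cell_lines)
    known = set(expr.cell_line_ids)
    for cid in wanted:
        if cid not in known:
            raise KeyError(f"no expression row for cell line {cid!r}")
    m_of = dict(zip(expr.cell_line_ids, m))

    networks = []
    others_cache = [np.arange(p) != l for l in range(p)]
    for cid in wanted:
        m_alpha = m_of[cid]
        K = gaussian_kernel(m, m_alpha, b)
        if K.sum() <= 0:
            raise ValueError(
                f"zero total kernel weight at cell line {cid!r}; increase the bandwidth"
            )
        coef = np.zeros((p, p))
        for l in range(p):
            others = others_cache[l]
            try:
                coef[l, others] = _fit_coefficients(X[:, others], X[:, l], K, config)
            except Exception as exc:  # re-raise with identity attached
                raise RuntimeError(
                    f"fit failed for target {expr.gene_ids[l]!r} at cell line {cid!r}"
                ) from exc
        networks.append(
            VaryingCoefficientNetwork(coef, cid, float(m_alpha), list(expr.gene_ids))
        )
    return networks


def networks_to_long_frame(networks: list[VaryingCoefficientNetwork]) -> pd.DataFrame:
    """Long-format edge table (cell_line, regulator, target, coefficient),
    nonzero coefficients only."""
    rows = []
    for net in networks:
        tgt_idx, reg_idx = np.nonzero(net.coefficients)
        for l, j in zip(tgt_idx, reg_idx):
            rows.append(
                (net.cell_line_id, net.gene_ids[j], net.gene_ids[l], net.coefficients[l, j])
            )
    return pd.DataFrame(rows, columns=["cell_line", "regulator", "target", "coefficient"])
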