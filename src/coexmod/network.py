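"""Weighted co-expression network construction and soft-threshold selection.

Pairwise gene correlations are turned into a weighted adjacency by the
soft-threshold power beta. The scale-free fit index R^2(beta) — a signed
coefficient of determination of the log-log regression of the degree
distribution — is evaluated over a beta grid, and beta is chosen as the
first grid value whose R^2 exceeds tau while the remaining suffix of the
curve has stabilized: every pairwise difference of R^2 values from that
point on stays below epsilon (a Cauchy-sequence-style criterion). With
epsilon = inf this reduces exactly to the classical "first beta with
R^2 > tau" rule.

The phi statistic summarizes the whole beta x R^2 curve as the area
under max(R^2, 0) divided by the area of the enclosing rectangle of
height 1; values near 1 mean the network converges sharply to a
scale-free degree distribution.

``SoftThresholdNetwork`` is the sklearn-style front end; the module
functions beneath it are pure and individually testable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "SoftThresholdNetwork",
    "correlation_matrix",
    "correlation_adjacency",
    "scale_free_fit",
    "beta_curve",
    "select_beta",
    "phi_statistic",
    "tom_similarity",
]


@dataclass
class NetworkConfig:
    """Soft-threshold search settings.

    beta_grid     candidate integer powers (strictly increasing, >=1)
    tau           R^2 threshold a candidate must exceed (default 0.8)
    epsilon       stabilization tolerance on R^2 differences (default 0.1)
    network_type  'unsigned' (|r|^beta) or 'signed' (((1+r)/2)^beta)
    correlation   'pearson' or 'spearman'
    n_bins        equal-width degree-histogram bins for the fit
    window        stabilization window length; None = full suffix
    """

    beta_grid: tuple[int, ...] = field(default_factory=lambda: tuple(range(1, 21)))
    tau: float = 0.8
    epsilon: float = 0.1
    network_type: str = "unsigned"
    correlation: str = "pearson"
    n_bins: int = 10
    window: int | None = None

    def __post_init__(self):
        grid = tuple(int(b) for b in self.beta_grid)
        if not grid or any(b < 1 for b in grid) or any(
            b2 <= b1 for b1, b2 in zip(grid, grid[1:])
        ):
            raise ValueError("beta_grid must be strictly increasing positive integers")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be 'pearson' or 'spearman'")
        self.beta_grid = grid


def correlation_matrix(expr: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    """Gene x gene correlation of a genes x samples frame."""
    X = expr.to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _power_adjacency(corr: np.ndarray, beta: int, network_type: str) -> np.ndarray:
    if beta < 1:
        raise ValueError("beta must be >= 1")
    base = np.abs(corr) if network_type == "unsigned" else (1.0 + corr) / 2.0
    adj = base**beta
    np.fill_diagonal(adj, 1.0)
    return adj


def correlation_adjacency(
    expr: pd.DataFrame, beta: int, cfg: NetworkConfig | None = None
) -> np.ndarray:
    """Soft-thresholded adjacency at a single beta.

    Unsigned: a = |r|^beta. Signed: correlations are first rescaled from
    [-1, 1] into [0, 1] via (1+r)/2, then powered. The diagonal is
    stored as 1 but excluded from all connectivity sums downstream.
    """
    cfg = cfg or NetworkConfig()
    corr = correlation_matrix(expr, cfg.correlation)
    return _power_adjacency(corr, beta, cfg.network_type)


def _connectivity(adjacency: np.ndarray) -> np.ndarray:
    return adjacency.sum(axis=1) - np.diag(adjacency)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index and mean connectivity of an adjacency.

    Connectivities are histogrammed into ``n_bins`` equal-width bins;
    over the non-empty bins, log10(frequency) is regressed on
    log10(mean connectivity). The index is -sign(slope) * R^2, so only
    decreasing (power-law-like) degree distributions score high.
    Returns ``(r2, mean_connectivity)``; degenerate degree distributions
    give r2 = 0 with a warning.
    """
    k = _connectivity(np.asarray(adjacency, dtype=float))
    mean_k = float(np.mean(k))
    if np.allclose(k, k[0]):
        warnings.warn("all connectivities equal; scale-free fit undefined, using 0")
        return 0.0, mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    n = k.size
    for b in range(n_bins):
        mask = which == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        kb = float(k[mask].mean())
        if kb <= 0:
            continue
        log_freq.append(np.log10(cnt / n))
        log_k.append(np.log10(kb))
    if len(log_k) < 2 or np.allclose(log_k, log_k[0]):
        warnings.warn("fewer than two usable degree bins; scale-free fit set to 0")
        return 0.0, mean_k
    res = stats.linregress(log_k, log_freq)
    r2 = -np.sign(res.slope) * res.rvalue**2
    return float(r2), mean_k


def beta_curve(expr: pd.DataFrame, cfg: NetworkConfig | None = None) -> pd.DataFrame:
    """Evaluate the scale-free fit over the beta grid.

    The base correlation matrix is computed once and powered per beta.
    Returns a frame (beta, r2, mean_connectivity) with the selected beta
    and phi in ``attrs``.
    """
    cfg = cfg or NetworkConfig()
    corr = correlation_matrix(expr, cfg.correlation)
    rows = []
    for beta in cfg.beta_grid:
        adj = _power_adjacency(corr, beta, cfg.network_type)
        r2, mean_k = scale_free_fit(adj, cfg.n_bins)
        rows.append({"beta": beta, "r2": r2, "mean_connectivity": mean_k})
    curve = pd.DataFrame(rows)
    curve.attrs["phi"] = phi_statistic(curve)
    curve.attrs["selected_beta"] = select_beta(curve, cfg)
    return curve


def select_beta(curve: pd.DataFrame, cfg: NetworkConfig | None = None) -> int | None:
    """Pick beta by threshold + suffix stabilization.

    Returns the smallest grid beta_i with r2(beta_i) > tau whose suffix
    {r2(beta_j): j >= i} (optionally truncated to ``cfg.window`` points)
    has max-min spread below epsilon; None when no candidate qualifies
    (the per-candidate suffix spreads are logged as a diagnostic).
    """
    cfg = cfg or NetworkConfig()
    betas = curve["beta"].to_numpy()
    r2 = curve["r2"].to_numpy(dtype=float)
    diagnostics = []
    for i in range(len(betas)):
        if not r2[i] > cfg.tau:
            continue
        suffix = r2[i:] if cfg.window is None else r2[i : i + cfg.window]
        spread = float(suffix.max() - suffix.min())
        diagnostics.append((int(betas[i]), spread))
        if spread < cfg.epsilon:
            return int(betas[i])
    if diagnostics:
        logger.info(
            "no beta stabilized; suffix spreads per candidate: %s", diagnostics
        )
    return None


def phi_statistic(curve: pd.DataFrame) -> float:
    """Area under max(r2, 0) over the beta range, normalized by the
    enclosing rectangle of height 1. A single-point grid returns its own
    clamped r2. Result lies in [0, 1]."""
    betas = curve["beta"].to_numpy(dtype=float)
    r2 = np.clip(curve["r2"].to_numpy(dtype=float), 0.0, None)
    if len(betas) == 1:
        return float(min(r2[0], 1.0))
    area = float(np.trapezoid(r2, betas))
    return area / float(betas[-1] - betas[0])


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu * a_uj; the diagonal is 1. Both the
    connectivities k and the shared-neighbor sums l exclude the diagonal.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    a_off = a.copy()
    np.fill_diagonal(a_off, 0.0)
    k = a_off.sum(axis=1)
    # l_ij over u != i, j: full product minus the two excluded terms
    l = a_off @ a_off  # includes u = i (a_ii=0) and u = j (a_jj=0) harmlessly
    num = l + a_off
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a_off
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


class SoftThresholdNetwork(BaseEstimator):
    """Fit a soft-thresholded co-expression network to samples x genes data.

    ``fit`` computes the gene-gene correlation, the beta x R^2 curve,
    the selected soft-threshold, phi, the adjacency at the selected beta
    and its topological overlap matrix.

    Parameters mirror :class:`NetworkConfig`; ``force_beta`` supplies a
    fallback used (and logged prominently) only when the stabilization
    rule selects nothing, or unconditionally if ``force_always=True``.

    Attributes
    ----------
    curve_ : DataFrame (beta, r2, mean_connectivity)
    beta_ : int
    phi_ : float
    adjacency_ : ndarray (genes x genes)
    tom_ : ndarray (genes x genes)
    """

    def __init__(
        self,
        beta_min: int = 1,
        beta_max: int = 20,
        tau: float = 0.8,
        epsilon: float = 0.1,
        network_type: str = "unsigned",
        correlation: str = "pearson",
        n_bins: int = 10,
        window: int | None = None,
        force_beta: int | None = None,
        force_always: bool = False,
    ):
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.tau = tau
        self.epsilon = epsilon
        self.network_type = network_type
        self.correlation = correlation
        self.n_bins = n_bins
        self.window = window
        self.force_beta = force_beta
        self.force_always = force_always

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            beta_grid=tuple(range(self.beta_min, self.beta_max + 1)),
            tau=self.tau,
            epsilon=self.epsilon,
            network_type=self.network_type,
            correlation=self.correlation,
            n_bins=self.n_bins,
            window=self.window,
        )

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3, ensure_min_features=3)
        cfg = self._config()
        expr = pd.DataFrame(X.T)  # genes x samples for the functional core
        self.curve_ = beta_curve(expr, cfg)
        self.phi_ = float(self.curve_.attrs["phi"])
        selected = self.curve_.attrs["selected_beta"]
        if self.force_always and self.force_beta is not None:
            logger.warning("soft-threshold FORCED to beta=%d", self.force_beta)
            selected = int(self.force_beta)
        elif selected is None:
            if self.force_beta is not None:
                logger.warning(
                    "no beta satisfied the stabilization rule; "
                    "FORCING beta=%d as requested", self.force_beta,
                )
                selected = int(self.force_beta)
            else:
                raise RuntimeError(
                    "no soft-threshold satisfied the stabilization rule; "
                    "set force_beta to override"
                )
        self.beta_ = int(selected)
        corr = correlation_matrix(expr, cfg.correlation)
        self.adjacency_ = _power_adjacency(corr, self.beta_, cfg.network_type)
        self.tom_ = tom_similarity(self.adjacency_)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict_tom(self, X):
        """Convenience: fit and return the TOM matrix."""
        return self.fit(X).tom_

    def __sklearn_is_fitted__(self):
        return hasattr(self, "tom_")
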