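"""Unsupervised gene selection by variance modeling, with optional VST.

Co-expression network inference assumes an informative subset of genes;
filtering by differential expression would break the scale-free topology
assumption, so selection here is unsupervised. Two estimators implement
the two stages:

``VarianceStabilizingTransformer``
    For count-like data whose variance grows quadratically with the mean
    (negative binomial, var = mu + alpha*mu^2), estimates a single
    dispersion ``alpha`` and applies the matching variance-stabilizing
    transform so that gene variances become comparable across the mean
    range.

``InverseGammaFilter``
    Removes the lowest-mean genes, fits an inverse-gamma distribution to
    the remaining per-gene sample variances by maximum likelihood, and
    keeps the genes whose variance is improbably HIGH under that fit
    (upper-tail p below the threshold).

Both follow scikit-learn conventions: arrays are samples x features
(i.e. samples x genes), fitted attributes end in an underscore, and the
estimators compose with sklearn pipelines. The module-level functions
``estimate_dispersion_and_vst`` and ``filter_genes`` wrap them for the
genes x samples pandas orientation used by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceStabilizingTransformer",
    "InverseGammaFilter",
    "FilterConfig",
    "estimate_dispersion_and_vst",
    "filter_genes",
]


class VarianceStabilizingTransformer(TransformerMixin, BaseEstimator):
    """Negative-binomial variance-stabilizing transform with common dispersion.

    The dispersion ``alpha`` in var = mu + alpha*mu^2 is estimated by
    least squares of (variance - mean) against mean^2 across genes and
    clamped at 0. The transform is

        x -> (2/sqrt(alpha)) * asinh(sqrt(alpha * x))   if alpha > 0
        x -> 2*sqrt(x)                                  if alpha = 0

    which is the classical VST for the negative binomial family (the
    alpha = 0 limit is the Poisson square-root transform).

    Parameters
    ----------
    alpha : float or None
        Fixed dispersion; when None (default) it is estimated in ``fit``.

    Attributes
    ----------
    alpha_ : float
        Dispersion used by ``transform``.
    """

    def __init__(self, alpha: float | None = None):
        self.alpha = alpha

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        if np.any(X < 0):
            raise ValueError(
                "negative values found: VST requires count-like, non-negative "
                "data; disable the transform for already-normalized input"
            )
        if self.alpha is not None:
            if self.alpha < 0:
                raise ValueError("alpha must be >= 0")
            self.alpha_ = float(self.alpha)
            return self
        mean = X.mean(axis=0)
        var = X.var(axis=0, ddof=1)
        denom = float(np.sum(mean**4))
        alpha = float(np.sum(mean**2 * (var - mean)) / denom) if denom > 0 else 0.0
        self.alpha_ = max(alpha, 0.0)
        return self

    def transform(self, X):
        check_is_fitted(self, "alpha_")
        X = check_array(X)
        if np.any(X < 0):
            raise ValueError("negative values: VST input must be non-negative")
        if self.alpha_ > 0:
            return (2.0 / np.sqrt(self.alpha_)) * np.arcsinh(np.sqrt(self.alpha_ * X))
        return 2.0 * np.sqrt(X)


class InverseGammaFilter(BaseEstimator):
    """Select high-variance genes under an inverse-gamma variance model.

    Per-gene sample variances are treated as draws from an inverse-gamma
    distribution; the filter keeps genes whose upper-tail probability
    under the fitted distribution falls below ``filter_pval``. Before the
    fit, the ``low_mean_fraction`` of genes with lowest mean expression
    is removed as likely noise. Zero-variance genes are excluded from the
    fit and never selected (their downstream correlations are undefined).

    Parameters
    ----------
    filter_pval : float, default 0.1
        Upper-tail probability threshold for selection.
    low_mean_fraction : float, default 0.25
        Fraction of lowest-mean genes removed before fitting.

    Attributes
    ----------
    means_, variances_, pvalues_ : ndarray (n_genes,)
        Per-gene statistics; p-values are NaN for genes dropped before
        the fit.
    support_ : boolean ndarray (n_genes,)
        Selected genes.
    shape_, scale_ : float
        Fitted inverse-gamma parameters (location fixed at 0).
    """

    def __init__(self, filter_pval: float = 0.1, low_mean_fraction: float = 0.25):
        self.filter_pval = filter_pval
        self.low_mean_fraction = low_mean_fraction

    def _validate_params_(self):
        if not 0 < self.filter_pval < 1:
            raise ValueError("filter_pval must lie in (0, 1)")
        if not 0 <= self.low_mean_fraction < 1:
            raise ValueError("low_mean_fraction must lie in [0, 1)")

    def fit(self, X, y=None):
        self._validate_params_()
        X = check_array(X, ensure_min_samples=3, ensure_min_features=2)
        n_genes = X.shape[1]
        means = X.mean(axis=0)
        variances = X.var(axis=0, ddof=1)

        keep = np.ones(n_genes, dtype=bool)
        n_drop = int(np.floor(self.low_mean_fraction * n_genes))
        if n_drop > 0:
            # stable argsort: ties drop the lower gene index first
            order = np.argsort(means, kind="stable")
            keep[order[:n_drop]] = False

        fit_mask = keep & (variances > 0)
        n_zero = int(np.sum(keep & (variances == 0)))
        if n_zero:
            logger.info("excluding %d zero-variance genes from the fit", n_zero)
        if fit_mask.sum() < 20:
            raise ValueError(
                f"only {int(fit_mask.sum())} genes available for the variance fit; "
                ">=20 required"
            )
        sample = variances[fit_mask]
        if np.allclose(sample, sample[0]):
            raise ValueError("variance distribution degenerate: all variances equal")

        try:
            shape, _, scale = stats.invgamma.fit(sample, floc=0)
            if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
                raise RuntimeError("invalid MLE solution")
        except Exception:  # MLE failure -> moment matching fallback
            m, v = float(np.mean(sample)), float(np.var(sample, ddof=1))
            shape = m**2 / v + 2.0
            scale = m * (shape - 1.0)
            logger.warning(
                "inverse-gamma MLE failed; using moment-matching fit "
                "(shape=%.3g, scale=%.3g)", shape, scale,
            )

        pvalues = np.full(n_genes, np.nan)
        pvalues[fit_mask] = stats.invgamma.sf(variances[fit_mask], shape, loc=0, scale=scale)

        self.means_ = means
        self.variances_ = variances
        self.pvalues_ = pvalues
        self.shape_ = float(shape)
        self.scale_ = float(scale)
        self.support_ = fit_mask & (pvalues < self.filter_pval)
        self.n_features_in_ = n_genes
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return X[:, self.support_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


@dataclass
class FilterConfig:
    """Gene-filter settings: thresholds and whether to apply VST first."""

    filter_pval: float = 0.1
    low_mean_fraction: float = 0.25
    apply_vst: bool = False


def estimate_dispersion_and_vst(expr: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Apply the NB variance-stabilizing transform to a genes x samples frame.

    Returns the transformed frame and the estimated common dispersion.
    """
    vst = VarianceStabilizingTransformer().fit(expr.to_numpy().T)
    out = pd.DataFrame(
        vst.transform(expr.to_numpy().T).T, index=expr.index, columns=expr.columns
    )
    return out, vst.alpha_


def filter_genes(expr: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Run the inverse-gamma variance filter on a genes x samples frame.

    Returns a per-gene table (gene, mean, variance, p, selected); the
    fitted shape/scale are attached under ``DataFrame.attrs``.
    """
    cfg = cfg or FilterConfig()
    est = InverseGammaFilter(
        filter_pval=cfg.filter_pval, low_mean_fraction=cfg.low_mean_fraction
    ).fit(expr.to_numpy().T)
    result = pd.DataFrame(
        {
            "gene": expr.index,
            "mean": est.means_,
            "variance": est.variances_,
            "p": est.pvalues_,
            "selected": est.support_,
        }
    )
    result.attrs["shape"] = est.shape_
    result.attrs["scale"] = est.scale_
    return result
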