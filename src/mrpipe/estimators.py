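"""Core two-sample MR causal estimators.

All three estimators operate on per-SNP summary effects of a harmonized
exposure/outcome pair and are regression-shaped, so they are exposed as
scikit-learn estimators: ``fit(X, y, sample_weight)`` takes the exposure
betas as a single-column ``X``, the outcome betas as ``y`` and the inverse
outcome variances ``1/se_out²`` as ``sample_weight``; fitted attributes
carry a trailing underscore and ``predict`` returns fitted outcome betas.

* :class:`IVWEstimator` — inverse-variance-weighted combination of Wald
  ratios, algebraically a weighted regression of outcome on exposure betas
  through the origin.  Fixed-effect SE or multiplicative random-effects SE
  (fixed SE times ``max(1, sqrt(Q/(k-1)))``); ``model="auto"`` selects
  random effects iff Cochran's Q has p < 0.05.
* :class:`EggerRegressor` — weighted least squares with an unconstrained
  intercept; the intercept estimates average directional pleiotropy, the
  slope a pleiotropy-adjusted causal effect.  SNPs are oriented so every
  exposure beta is non-negative before fitting.
* :class:`WeightedMedianEstimator` — median of the Wald ratios under
  cumulative inverse-variance weights, consistent when instruments carrying
  at least half the weight are valid; SE by seeded parametric bootstrap.

Convenience functions (:func:`ivw`, :func:`egger`, :func:`weighted_median`,
:func:`wald_ratios`) wrap the classes for :class:`~mrpipe.instruments.HarmonizedSet`
inputs and return :class:`MRResult` records with OR/CI reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .instruments import HarmonizedSet

__all__ = [
    "MRResult",
    "PleiotropyResult",
    "WaldRatioSet",
    "IVWEstimator",
    "EggerRegressor",
    "WeightedMedianEstimator",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "to_odds_ratio",
]

_P_FLOOR = np.nextafter(0.0, 1.0)


def _clip_p(p: float) -> float:
    return float(min(max(p, _P_FLOOR), 1.0))


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """(OR, CI low, CI high) = exp(beta), exp(beta ± z·se) at the given level."""
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


@dataclass(frozen=True)
class MRResult:
    """A causal estimate with its OR rendering (Table-style row)."""

    method: str  # IVW | Egger | WeightedMedian | WaldRatio
    model: str   # fixed | random | n/a
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int

    @classmethod
    def from_beta(cls, method: str, model: str, beta: float, se: float,
                  pval: float, n_snp: int, level: float = 0.95) -> "MRResult":
        or_, lo, hi = to_odds_ratio(beta, se, level)
        return cls(method=method, model=model, beta=float(beta), se=float(se),
                   pval=_clip_p(pval), or_=or_, ci_low=lo, ci_high=hi, n_snp=n_snp)


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test for average directional pleiotropy."""

    intercept: float
    se: float
    pval: float


@dataclass(frozen=True)
class WaldRatioSet:
    theta: np.ndarray
    se_theta: np.ndarray
    weight: np.ndarray
    snp_ids: tuple[str, ...]
    dropped: tuple[str, ...]  # zero exposure-beta SNPs


def wald_ratios(h: HarmonizedSet) -> WaldRatioSet:
    """Per-SNP ratio estimates theta = beta_out/beta_exp.

    First-order SE se_out/|beta_exp| (exposure-side noise ignored), weight
    1/se_theta².  SNPs with beta_exp = 0 are dropped with a report; an
    all-zero exposure is a hard error.
    """
    nonzero = h.beta_exp != 0.0
    if not np.any(nonzero):
        raise ValueError("all exposure betas are zero; no Wald ratios defined")
    dropped = tuple(np.array(h.snp_ids)[~nonzero])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} SNP(s) with zero exposure beta")
    bx, by, so = h.beta_exp[nonzero], h.beta_out[nonzero], h.se_out[nonzero]
    theta = by / bx
    se_theta = so / np.abs(bx)
    return WaldRatioSet(
        theta=theta, se_theta=se_theta, weight=1.0 / se_theta**2,
        snp_ids=tuple(np.array(h.snp_ids)[nonzero]), dropped=dropped,
    )


def _validate_xyw(X, y, sample_weight):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] != 1:
        raise ValueError("X must be a single column of exposure betas")
    x = X[:, 0]
    y = np.asarray(y, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y must match X in length")
    if sample_weight is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape != y.shape or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("sample_weight must be positive, finite, same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite betas")
    return x, y, w


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance-weighted MR estimate.

    Parameters
    ----------
    model : {"fixed", "random", "auto"}
        SE model.  ``random`` applies the multiplicative overdispersion
        factor ``max(1, sqrt(Q/(k-1)))`` to the fixed-effect SE; ``auto``
        uses random effects iff Cochran's Q p-value < 0.05.

    Fitted attributes: ``beta_``, ``se_``, ``pval_`` (two-sided normal),
    ``q_``, ``q_pval_``, ``model_used_``, ``n_snp_``.
    """

    def __init__(self, model: str = "auto"):
        self.model = model

    def fit(self, X, y, sample_weight=None):
        if self.model not in ("fixed", "random", "auto"):
            raise ValueError(f"unknown model {self.model!r}")
        x, y, w_out = _validate_xyw(X, y, sample_weight)
        nonzero = x != 0.0
        x, y, w_out = x[nonzero], y[nonzero], w_out[nonzero]
        k = x.size
        if k < 1:
            raise ValueError("IVW requires at least one nonzero-exposure instrument")
        theta = y / x
        w = x**2 * w_out  # = 1/se_theta² with se_theta = se_out/|beta_exp|
        beta = float(np.sum(w * theta) / np.sum(w))
        se_fixed = float(np.sqrt(1.0 / np.sum(w)))
        q = float(np.sum(w * (theta - beta) ** 2))
        if k >= 2:
            q_pval = _clip_p(stats.chi2.sf(q, k - 1))
            mult = max(1.0, np.sqrt(q / (k - 1)))
        else:
            warnings.warn("single instrument: IVW degrades to the Wald ratio")
            q_pval, mult = 1.0, 1.0
        if self.model == "fixed":
            used = "fixed"
        elif self.model == "random":
            used = "random"
        else:
            used = "random" if q_pval < 0.05 else "fixed"
        se = se_fixed * (mult if used == "random" else 1.0)
        self.n_snp_ = int(k)
        self.beta_ = beta
        self.se_fixed_ = se_fixed
        self.se_ = float(se)
        self.q_ = q
        self.q_pval_ = q_pval
        self.model_used_ = used
        self.pval_ = _clip_p(2.0 * stats.norm.sf(abs(beta) / se))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X[:, 0] * self.beta_


class EggerRegressor(RegressorMixin, BaseEstimator):
    """MR-Egger: weighted regression of outcome betas on exposure betas
    with an unconstrained intercept.

    SNPs are oriented so exposure betas are non-negative before fitting
    (Egger is not invariant to allele orientation).  Slope and intercept
    SEs are the WLS SEs; when ``overdispersion`` is true the residual
    scale factor is floored at 1 (``max(1, sqrt(Q_egger/(k-2)))``), the
    convention of the established two-sample-MR software family.
    P-values use the t distribution with k-2 df.

    Fitted attributes: ``beta_`` (slope), ``se_``, ``pval_``,
    ``intercept_``, ``intercept_se_``, ``intercept_pval_``, ``q_``,
    ``q_pval_``, ``n_snp_``.
    """

    def __init__(self, overdispersion: bool = True):
        self.overdispersion = overdispersion

    def fit(self, X, y, sample_weight=None):
        x, y, w = _validate_xyw(X, y, sample_weight)
        k = x.size
        if k < 3:
            raise ValueError("Egger requires >= 3 instruments")
        sign = np.where(x < 0, -1.0, 1.0)
        x, y = x * sign, y * sign
        wls = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        resid_q = float(np.sum(w * wls.resid**2))
        phi = resid_q / (k - 2)
        scale = max(1.0, phi) if self.overdispersion else phi
        # WLS parameter covariance with the residual scale replaced by ours
        cov_unit = np.asarray(wls.normalized_cov_params)
        ses = np.sqrt(np.diag(cov_unit) * scale)
        self.n_snp_ = int(k)
        self.intercept_ = float(wls.params[0])
        self.beta_ = float(wls.params[1])
        self.intercept_se_ = float(ses[0])
        self.se_ = float(ses[1])
        self.q_ = resid_q
        self.q_pval_ = _clip_p(stats.chi2.sf(resid_q, k - 2))
        self.pval_ = _clip_p(2.0 * stats.t.sf(abs(self.beta_) / self.se_, k - 2))
        self.intercept_pval_ = _clip_p(
            2.0 * stats.t.sf(abs(self.intercept_) / self.intercept_se_, k - 2)
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X[:, 0] * self.beta_


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative standardized weights
    s_j = (cumsum(w) - w_j/2)/sum(w), linear interpolation at s = 0.5."""
    order = np.argsort(theta)
    th, ww = theta[order], w[order]
    s = (np.cumsum(ww) - ww / 2.0) / np.sum(ww)
    return float(np.interp(0.5, s, th))


class WeightedMedianEstimator(RegressorMixin, BaseEstimator):
    """Weighted-median MR estimate with parametric-bootstrap SE.

    The point estimate is the inverse-variance-weighted median of the Wald
    ratios; it is consistent when valid instruments carry more than half
    the total weight.  The SE is the standard deviation of ``n_boot``
    re-estimates with theta_j resampled from Normal(theta_j, se_theta_j),
    seeded by ``random_state``.
    """

    def __init__(self, n_boot: int = 1000, random_state: int = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        x, y, w_out = _validate_xyw(X, y, sample_weight)
        nonzero = x != 0.0
        x, y, w_out = x[nonzero], y[nonzero], w_out[nonzero]
        k = x.size
        if k < 3:
            raise ValueError("weighted median requires >= 3 instruments")
        theta = y / x
        se_theta = 1.0 / (np.abs(x) * np.sqrt(w_out))
        w = 1.0 / se_theta**2
        beta = _weighted_median(theta, w)
        rng = np.random.default_rng(self.random_state)
        draws = rng.normal(theta, se_theta, size=(self.n_boot, k))
        order = np.argsort(draws, axis=1)
        th = np.take_along_axis(draws, order, axis=1)
        ww = np.broadcast_to(w, (self.n_boot, k))
        ww = np.take_along_axis(ww, order, axis=1)
        s = (np.cumsum(ww, axis=1) - ww / 2.0) / np.sum(ww, axis=1, keepdims=True)
        boots = np.array([np.interp(0.5, s[b], th[b]) for b in range(self.n_boot)])
        self.n_snp_ = int(k)
        self.beta_ = beta
        self.se_ = float(np.std(boots, ddof=1))
        self.pval_ = _clip_p(2.0 * stats.norm.sf(abs(beta) / self.se_))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X[:, 0] * self.beta_


def _xyw(h: HarmonizedSet):
    return h.beta_exp[:, None], h.beta_out, 1.0 / h.se_out**2


def ivw(h: HarmonizedSet, model: str = "auto", level: float = 0.95) -> MRResult:
    """IVW estimate for a harmonized set; see :class:`IVWEstimator`."""
    est = IVWEstimator(model=model).fit(*_xyw(h))
    method = "IVW" if est.n_snp_ > 1 else "WaldRatio"
    model_used = est.model_used_ if est.n_snp_ > 1 else "n/a"
    return MRResult.from_beta(method, model_used, est.beta_, est.se_,
                              est.pval_, est.n_snp_, level)


def egger(
    h: HarmonizedSet, overdispersion: bool = True, level: float = 0.95
) -> tuple[MRResult, PleiotropyResult]:
    """MR-Egger slope and intercept for a harmonized set."""
    est = EggerRegressor(overdispersion=overdispersion).fit(*_xyw(h))
    res = MRResult.from_beta("Egger", "random" if overdispersion else "fixed",
                             est.beta_, est.se_, est.pval_, est.n_snp_, level)
    pleio = PleiotropyResult(intercept=est.intercept_, se=est.intercept_se_,
                             pval=est.intercept_pval_)
    return res, pleio


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> MRResult:
    """Weighted-median estimate for a harmonized set."""
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(*_xyw(h))
    return MRResult.from_beta("WeightedMedian", "n/a", est.beta_, est.se_,
                              est.pval_, est.n_snp_, level)
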