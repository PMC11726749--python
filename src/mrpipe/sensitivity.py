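"""Heterogeneity and horizontal-pleiotropy diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
fixed-effect IVW estimate (df = k-1) or of outcome betas around the
MR-Egger fit (df = k-2), referenced to the chi-square upper tail; a Q
p-value below 0.05 selects the multiplicative random-effects model.

MR-PRESSO is a simulation-based residual-sum-of-squares framework with
three stages: a *global* test of overall horizontal pleiotropy, a per-SNP
*outlier* test (run only when the global test is significant), and a
*distortion* test of whether removing the flagged outliers materially
shifts the causal estimate.  Expected outcome betas use leave-one-out IVW
estimates so an outlier cannot contaminate its own expectation, and all
empirical p-values use the (1+b)/(1+n) estimator so they are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .estimators import EggerRegressor, IVWEstimator, MRResult, _clip_p, _validate_xyw
from .instruments import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "MRPresso",
    "cochran_q",
    "select_model",
    "presso_global",
    "presso_outlier",
    "presso_distortion",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # IVW | Egger
    q: float
    df: int
    pval: float


def cochran_q(h: HarmonizedSet, method: str = "IVW") -> HeterogeneityResult:
    """Cochran's Q for the IVW (df = k-1) or Egger (df = k-2) fit."""
    X, y, w = h.beta_exp[:, None], h.beta_out, 1.0 / h.se_out**2
    if method == "IVW":
        if h.n_snp < 2:
            raise ValueError("Cochran's Q (IVW) requires >= 2 instruments")
        est = IVWEstimator(model="fixed").fit(X, y, sample_weight=w)
        q, df = est.q_, est.n_snp_ - 1
    elif method == "Egger":
        if h.n_snp < 3:
            raise ValueError("Cochran's Q (Egger) requires >= 3 instruments")
        est = EggerRegressor().fit(X, y, sample_weight=w)
        q, df = est.q_, est.n_snp_ - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return HeterogeneityResult(method=method, q=float(q), df=df,
                               pval=_clip_p(stats.chi2.sf(q, df)))


def select_model(q: HeterogeneityResult) -> str:
    """Random-effects iff Q p-value < 0.05 (p >= 0.05 means no heterogeneity)."""
    return "random" if q.pval < 0.05 else "fixed"


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_snp_ids: tuple[str, ...] = ()
    per_snp_pvals: tuple[float, ...] = ()
    distortion_pval: float | None = None
    estimate_before: MRResult | None = None
    estimate_after: MRResult | None = None
    n_sim: int = 0
    seed: int = 0


def _loo_ivw(x, y, w):
    """Leave-one-out IVW slopes, vectorized: regression through the origin."""
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    denom = sxx - w * x * x
    if np.any(denom <= 0):
        raise ValueError("leave-one-out IVW undefined (a single SNP carries all weight)")
    return (sxy - w * x * y) / denom


class MRPresso(BaseEstimator):
    """MR-PRESSO global/outlier/distortion tests as an outlier detector.

    ``fit(X, y, sample_weight)`` takes exposure betas, outcome betas and
    inverse outcome variances, like the MR estimator classes.

    Fitted attributes: ``rss_obs_``, ``global_pval_``, ``outlier_mask_``
    (empty by contract unless the global test is significant),
    ``per_snp_pvals_`` (Bonferroni-adjusted), ``distortion_pval_``,
    ``beta_before_``, ``beta_after_``.
    """

    def __init__(self, n_sim: int = 1000, n_boot: int = 1000,
                 significance: float = 0.05, random_state: int = 0):
        self.n_sim = n_sim
        self.n_boot = n_boot
        self.significance = significance
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        x, y, w = _validate_xyw(X, y, sample_weight)
        k = x.size
        if k < 4:
            raise ValueError("MR-PRESSO requires >= 4 instruments")
        rng = np.random.default_rng(self.random_state)
        se_out = 1.0 / np.sqrt(w)

        loo = _loo_ivw(x, y, w)
        contrib_obs = w * (y - loo * x) ** 2
        self.rss_obs_ = float(np.sum(contrib_obs))

        # simulated datasets under the no-pleiotropy expectation
        mu = loo * x
        y_sim = rng.normal(mu, se_out, size=(self.n_sim, k))
        sxx = np.sum(w * x * x)
        sxy_sim = y_sim @ (w * x)  # (n_sim,)
        denom = sxx - w * x * x    # (k,)
        loo_sim = (sxy_sim[:, None] - (w * x) * y_sim) / denom
        contrib_sim = w * (y_sim - loo_sim * x) ** 2  # (n_sim, k)
        rss_sim = contrib_sim.sum(axis=1)

        self.global_pval_ = float(
            (1 + np.sum(rss_sim >= self.rss_obs_)) / (self.n_sim + 1)
        )

        self.outlier_mask_ = np.zeros(k, dtype=bool)
        self.per_snp_pvals_ = np.full(k, np.nan)
        self.distortion_pval_ = None
        self.beta_before_ = None
        self.beta_after_ = None

        if self.global_pval_ <= self.significance:
            p_raw = (1 + np.sum(contrib_sim >= contrib_obs, axis=0)) / (self.n_sim + 1)
            p_adj = np.minimum(1.0, p_raw * k)  # Bonferroni over instruments
            self.per_snp_pvals_ = p_adj
            self.outlier_mask_ = p_adj <= self.significance

            if self.outlier_mask_.any() and (~self.outlier_mask_).sum() >= 2:
                self._distortion(x, y, w, rng)
        return self

    def _distortion(self, x, y, w, rng):
        mask = self.outlier_mask_
        n_out = int(mask.sum())
        keep = ~mask

        def _beta(sel):
            return IVWEstimator(model="fixed").fit(
                x[sel, None], y[sel], sample_weight=w[sel]
            ).beta_

        before = _beta(np.ones_like(mask))
        after = _beta(keep)
        if after == 0:
            raise ZeroDivisionError("distortion statistic undefined: estimate_after is 0")
        stat_obs = (before - after) / abs(after)
        self.beta_before_ = float(before)
        self.beta_after_ = float(after)

        non_out_idx = np.flatnonzero(keep)
        if len(non_out_idx) - n_out < 2:
            # cannot draw removal subsets leaving >= 2 SNPs; p undefined
            self.distortion_pval_ = None
            self.distortion_stat_ = float(stat_obs)
            return
        stats_boot = np.empty(self.n_boot)
        for b in range(self.n_boot):
            # null removal: equally many random non-outliers from the full set
            drop = rng.choice(non_out_idx, size=n_out, replace=False)
            sel = np.ones_like(mask)
            sel[drop] = False
            b_sub = _beta(sel)
            stats_boot[b] = np.inf if b_sub == 0 else (before - b_sub) / abs(b_sub)
        self.distortion_stat_ = float(stat_obs)
        self.distortion_pval_ = float(
            (1 + np.sum(np.abs(stats_boot) >= abs(stat_obs))) / (self.n_boot + 1)
        )


def _fit_presso(h: HarmonizedSet, n_sim: int, n_boot: int, seed: int) -> MRPresso:
    return MRPresso(n_sim=n_sim, n_boot=n_boot, random_state=seed).fit(
        h.beta_exp[:, None], h.beta_out, sample_weight=1.0 / h.se_out**2
    )


def presso_global(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """MR-PRESSO global test of horizontal pleiotropy."""
    det = _fit_presso(h, n_sim, 2, seed)
    return PressoResult(rss_obs=det.rss_obs_, global_pval=det.global_pval_,
                        n_sim=n_sim, seed=seed)


def presso_outlier(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """MR-PRESSO per-SNP outlier test (empty unless the global test rejects)."""
    det = _fit_presso(h, n_sim, 2, seed)
    ids = tuple(np.array(h.snp_ids)[det.outlier_mask_])
    return PressoResult(
        rss_obs=det.rss_obs_, global_pval=det.global_pval_,
        outlier_snp_ids=ids, per_snp_pvals=tuple(det.per_snp_pvals_),
        n_sim=n_sim, seed=seed,
    )


def presso_distortion(
    h: HarmonizedSet, outliers: list[str], n_boot: int = 1000, seed: int = 0
) -> PressoResult:
    """MR-PRESSO distortion test for a given outlier list.

    Compares the IVW estimate before and after removing ``outliers``; the
    null distribution removes equally many random non-outlier SNPs.
    """
    if not outliers:
        raise ValueError("distortion test requires a non-empty outlier list")
    mask = np.isin(np.array(h.snp_ids), np.array(outliers))
    if (~mask).sum() < 2:
        raise ValueError("estimate_after undefined for < 2 remaining SNPs")
    x, y, w = h.beta_exp, h.beta_out, 1.0 / h.se_out**2
    rng = np.random.default_rng(seed)

    def _res(sel) -> MRResult:
        hh = h.subset(np.flatnonzero(sel))
        from .estimators import ivw
        return ivw(hh, model="fixed")

    before = _res(np.ones_like(mask, dtype=bool))
    after = _res(~mask)
    if after.beta == 0:
        raise ZeroDivisionError("distortion statistic undefined: estimate_after is 0")
    stat_obs = (before.beta - after.beta) / abs(after.beta)

    non_out_idx = np.flatnonzero(~mask)
    n_out = int(mask.sum())
    if len(non_out_idx) - n_out < 2:
        raise ValueError("not enough non-outlier SNPs to bootstrap the null")
    est_before = before.beta
    stats_boot = np.empty(n_boot)
    for b in range(n_boot):
        # null removal: equally many random non-outliers from the full set
        drop = rng.choice(non_out_idx, size=n_out, replace=False)
        sel = np.ones_like(mask, dtype=bool)
        sel[drop] = False
        xb, yb, wb = x[sel], y[sel], w[sel]
        wr = xb**2 * wb
        b_sub = float(np.sum(wr * (yb / xb)) / np.sum(wr))
        stats_boot[b] = np.inf if b_sub == 0 else (est_before - b_sub) / abs(b_sub)
    pval = float((1 + np.sum(np.abs(stats_boot) >= abs(stat_obs))) / (n_boot + 1))
    return PressoResult(
        rss_obs=np.nan, global_pval=1.0,
        outlier_snp_ids=tuple(outliers),
        distortion_pval=pval, estimate_before=before, estimate_after=after,
        n_sim=n_boot, seed=seed,
    )
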