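"""Monte-Carlo calibration and recovery experiments.

Each function runs a seeded simulation study through the full pipeline
(p-value selection, clumping, harmonization, estimation) and returns the
summary metrics a practitioner would use to validate an MR implementation:
type-I error and Cochran's-Q calibration under the global null, recovery
of a planted mediated effect by the two-step analysis, robustness of the
weighted median under directional pleiotropy, MR-Egger intercept recovery,
and MR-PRESSO detection/calibration.  Study sizes follow the desk-scale
designs described in docs/methods.md; every function is deterministic
given its ``seed``.
"""

from __future__ import annotations

import math

import numpy as np

from .estimators import egger, ivw, weighted_median
from .gwas_io import attach_positions
from .instruments import InstrumentConfig, clump, harmonize, select_by_pvalue
from .mediation import run_two_step
from .sensitivity import MRPresso, cochran_q, presso_distortion
from .simulate import SimulationConfig, simulate_triplet
from .worked_example import decompose_pair

__all__ = [
    "worked_example_metrics",
    "null_calibration",
    "twostep_recovery",
    "pleiotropy_robustness",
    "egger_intercept_recovery",
    "presso_behaviour",
]

_ICFG = InstrumentConfig()


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _harmonized(sim_cfg: SimulationConfig):
    t = simulate_triplet(sim_cfg)
    sel = select_by_pvalue(t.exposure, _ICFG)
    if len(sel) < 2:
        return None, t
    cl = clump(sel, attach_positions(t.ld, sel), _ICFG)
    return harmonize(cl, t.outcome, _ICFG), t


def worked_example_metrics() -> dict:
    """Effect decomposition of the bundled published ORs (percent scale)."""
    asv022 = decompose_pair("asv022", "GCST90301994")
    bac = decompose_pair("bacillales", "GCST90302151")
    clo = decompose_pair("clostridiales", "GCST90302078")
    return {
        "asv022_total_pct": asv022.total_pct,
        "asv022_indirect_pct": asv022.indirect_pct,
        "asv022_direct_pct": asv022.direct_pct,
        "asv022_mediator_pct": asv022.proportion_pct,
        "bacillales_total_pct": bac.total_pct,
        "clostridiales_total_pct": clo.total_pct,
    }


def null_calibration(n_reps: int = 2000, seed: int = 0) -> dict:
    """IVW type-I error at nominal 0.05 and Cochran's-Q mean under the null.

    Null design: 50 independent SNPs, n = 100,000 per study, no causal
    effect, no pleiotropy (the generator defaults).
    """
    seeds = _replicate_seeds(seed, n_reps)
    rejections, q_minus_df, dfs = 0, [], []
    n_valid = 0
    for s in seeds:
        h, _ = _harmonized(SimulationConfig(seed=int(s)))
        if h is None:
            continue
        n_valid += 1
        rejections += ivw(h, model="auto").pval <= 0.05
        q = cochran_q(h, "IVW")
        q_minus_df.append(q.q - q.df)
        dfs.append(q.df)
    return {
        "type1_error": rejections / n_valid,
        "q_mean_minus_df": float(np.mean(q_minus_df)),
        "mean_df": float(np.mean(dfs)),
        "n": n_valid,
    }


#: Two-step recovery study conditions: a genuine mediated effect with the
#: mediator's own genetic component (see docs/methods.md).
TWOSTEP_CFG = dict(n_snps=150, beta_exp_med=0.2, beta_med_out=0.3,
                   beta_exp_out_direct=0.1, pleiotropy_sd=0.1)
TWOSTEP_TRUTH = dict(total=0.16, indirect=0.06, direct=0.10)


def twostep_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Mean recovered total/indirect/direct effects and total-effect CI coverage."""
    seeds = _replicate_seeds(seed, n_reps)
    tot, ind, dire, cov = [], [], [], 0
    for s in seeds:
        t = simulate_triplet(SimulationConfig(seed=int(s), **TWOSTEP_CFG))
        res = run_two_step(t.exposure, t.mediator, t.outcome, t.ld, t.ld,
                           n_boot=2, seed=int(s) % 1000)
        m = res.mediation
        tot.append(m.total)
        ind.append(m.indirect)
        dire.append(m.direct)
        ci = res.total_stage.ivw
        cov += ci.ci_low <= math.exp(TWOSTEP_TRUTH["total"]) <= ci.ci_high
    n = len(tot)

    def _summ(v):
        v = np.asarray(v)
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n))

    out = {}
    for name, v in (("total", tot), ("indirect", ind), ("direct", dire)):
        out[f"{name}_mean"], out[f"{name}_mc_se"] = _summ(v)
    out["coverage"] = cov / n
    out["n"] = n
    return out


def pleiotropy_robustness(n_reps: int = 500, seed: int = 0) -> dict:
    """|bias| of weighted median vs IVW with 40% directionally pleiotropic SNPs.

    40% of the SNPs receive a constant +0.02 outcome offset on top of a
    true direct effect of 0.1.
    """
    seeds = _replicate_seeds(seed, n_reps)
    truth = 0.1
    b_ivw, b_wm = [], []
    for s in seeds:
        h, _ = _harmonized(SimulationConfig(
            seed=int(s), beta_exp_out_direct=truth,
            n_outlier_snps=20, outlier_effect=0.02))
        if h is None or h.n_snp < 3:
            continue
        b_ivw.append(ivw(h).beta - truth)
        b_wm.append(weighted_median(h, n_boot=16, seed=int(s) % 1000).beta - truth)
    return {
        "ivw_abs_bias": abs(float(np.mean(b_ivw))),
        "wm_abs_bias": abs(float(np.mean(b_wm))),
        "n": len(b_ivw),
    }


def egger_intercept_recovery(n_reps: int = 500, seed: int = 0,
                             pleiotropy_mean: float = 0.01) -> dict:
    """MR-Egger intercept under directional pleiotropy with InSIDE held.

    The chain is collapsed to the univariate model (beta_exp_med = 0,
    beta_med_out = 1) so the pleiotropy term hits the outcome directly.
    """
    seeds = _replicate_seeds(seed, n_reps)
    ints = []
    for s in seeds:
        h, _ = _harmonized(SimulationConfig(
            seed=int(s), beta_exp_med=0.0, beta_med_out=1.0,
            beta_exp_out_direct=0.05,
            pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=0.005))
        if h is None or h.n_snp < 3:
            continue
        ints.append(egger(h)[1].intercept)
    ints = np.asarray(ints)
    return {
        "intercept_mean": float(ints.mean()),
        "mc_se": float(ints.std(ddof=1) / np.sqrt(len(ints))),
        "truth": pleiotropy_mean,
        "n": len(ints),
    }


def presso_behaviour(n_detect: int = 200, n_null: int = 200,
                     n_distortion: int = 100, n_sim: int = 1000,
                     seed: int = 0) -> dict:
    """MR-PRESSO detection of a planted outlier plus null calibration.

    Detection: one SNP receives a +0.06 outcome offset (ten times the
    median simulated outcome SE); the rate is the fraction of replicates,
    among those where the planted SNP survives instrument selection, in
    which the outlier test flags it.  Null rejection: global-test rate at
    0.05 on null data.  Distortion specificity: rejection rate of the
    distortion test when a single random non-influential SNP is removed
    from null data.
    """
    seeds = _replicate_seeds(seed, n_detect + n_null + n_distortion)
    hits = n_cond = 0
    for s in seeds[:n_detect]:
        h, t = _harmonized(SimulationConfig(
            seed=int(s), beta_exp_out_direct=0.1,
            n_outlier_snps=1, outlier_effect=0.06))
        planted = t.truth.outlier_snp_ids[0]
        if h is None or planted not in h.snp_ids:
            continue
        n_cond += 1
        det = MRPresso(n_sim=n_sim, n_boot=20, random_state=int(s) % 1000).fit(
            h.beta_exp[:, None], h.beta_out, 1.0 / h.se_out**2)
        hits += planted in set(np.array(h.snp_ids)[det.outlier_mask_])

    null_rej = n_valid = 0
    for s in seeds[n_detect:n_detect + n_null]:
        h, _ = _harmonized(SimulationConfig(seed=int(s)))
        if h is None or h.n_snp < 4:
            continue
        n_valid += 1
        det = MRPresso(n_sim=n_sim, n_boot=2, random_state=int(s) % 1000).fit(
            h.beta_exp[:, None], h.beta_out, 1.0 / h.se_out**2)
        null_rej += det.global_pval_ <= 0.05

    dist_rej = n_dist = 0
    for s in seeds[n_detect + n_null:]:
        h, _ = _harmonized(SimulationConfig(seed=int(s)))
        if h is None or h.n_snp < 5:
            continue
        n_dist += 1
        victim = h.snp_ids[int(s) % h.n_snp]
        r = presso_distortion(h, [victim], n_boot=200, seed=int(s) % 1000)
        dist_rej += r.distortion_pval <= 0.05
    return {
        "detection_rate": hits / n_cond,
        "n_detect": n_cond,
        "null_global_rejection": null_rej / n_valid,
        "n_null": n_valid,
        "distortion_false_rejection": dist_rej / n_dist,
        "n_distortion": n_dist,
    }
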