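"""Synthetic GWAS summary statistics under a causal chain.

The generator emulates three independent GWAS — exposure, mediator and
outcome — whose true per-SNP effects follow the two-step structure

    exposure:  gamma_j                    (instrument effects)
    mediator:  gamma_j * b_xm + alpha_j   (alpha = mediator-side pleiotropy /
                                           the mediator's own genetics)
    outcome:   gamma_j * (b_xm * b_my + b_xy)
               + alpha_j * b_my + outlier_j

where ``b_xm`` is the exposure→mediator effect, ``b_my`` the
mediator→outcome effect and ``b_xy`` the direct exposure→outcome effect,
all on a log-odds scale for the outcome so OR = exp(beta).  Observed betas
add sampling noise Normal(0, se_j) with the standard summary-level
standard error se_j = 1/sqrt(2 n maf_j (1 - maf_j)); p-values are the
two-sided normal tail of beta/se.

Instrument effects are oriented non-negative: the effect allele of every
SNP is the exposure-increasing allele, the frame harmonized exposure data
conventionally occupy and the one in which "directional" pleiotropy
(nonzero ``pleiotropy_mean``) is meaningful for MR-Egger.  A configurable
fraction of mediator/outcome rows is reported with swapped allele
orientation (beta negated, eaf mirrored) so downstream harmonization is
exercised, not assumed.

Setting ``beta_exp_med = 0`` and ``beta_med_out = 1`` collapses the chain
to the classic univariate MR model with direct pleiotropy alpha_j on the
outcome, under which the MR-Egger intercept estimates ``pleiotropy_mean``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .gwas_io import LDMatrix, SNPAssociation

__all__ = ["SimulationConfig", "SimulatedTriplet", "simulate_triplet", "simulate_ld_blocks"]

# non-palindromic ordered allele pairs (palindromic A/T and C/G pairs are
# excluded so that simulated instruments never hit the ambiguity filter;
# palindromic handling is tested on handcrafted records)
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one triplet of GWAS summary statistics.

    Defaults encode the desk-scale calibration conditions: 50 independent
    SNPs, 100,000 samples per study, moderately strong instruments
    (variance 0.01 of true SNP→exposure effects, mean F well above the
    weak-instrument screen), no causal effects, no pleiotropy, no planted
    outliers.
    """

    n_snps: int = 50
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    instrument_strength: float = 0.01
    beta_exp_med: float = 0.0
    beta_med_out: float = 0.0
    beta_exp_out_direct: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outlier_snps: int = 0
    outlier_effect: float = 0.0
    ld_block_size: int = 1
    ld_within_block_r2: float = 0.0
    maf_low: float = 0.1
    maf_high: float = 0.4
    swap_fraction: float = 0.25
    block_spacing_bp: int = 20_000_000
    within_block_spacing_bp: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"non-finite config parameter {name}={v}")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if self.n_outlier_snps > self.n_snps:
            raise ValueError("n_outlier_snps exceeds n_snps")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0 <= self.ld_within_block_r2 < 1):
            raise ValueError("ld_within_block_r2 must lie in [0, 1)")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")
        if not (0 <= self.swap_fraction <= 1):
            raise ValueError("swap_fraction must lie in [0, 1]")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n <= 0:
                raise ValueError("sample sizes must be positive")


@dataclass(frozen=True)
class Truth:
    """Generating parameters recorded alongside a simulated triplet."""

    total: float
    indirect: float
    direct: float
    step1: float
    step2: float
    outlier_snp_ids: tuple[str, ...]
    gamma: np.ndarray
    alpha: np.ndarray


@dataclass(frozen=True)
class SimulatedTriplet:
    exposure: list[SNPAssociation]
    mediator: list[SNPAssociation]
    outcome: list[SNPAssociation]
    ld: LDMatrix
    truth: Truth
    config: SimulationConfig = field(repr=False, default=None)


def _positions(cfg: SimulationConfig) -> np.ndarray:
    """Consecutive blocks: tight within-block spacing, > clumping-window gaps between."""
    idx = np.arange(cfg.n_snps)
    block = idx // cfg.ld_block_size
    within = idx % cfg.ld_block_size
    return 1 + block * cfg.block_spacing_bp + within * cfg.within_block_spacing_bp


def simulate_ld_blocks(config: SimulationConfig) -> LDMatrix:
    """Block-diagonal r² matrix: ``ld_within_block_r2`` inside consecutive
    blocks of ``ld_block_size`` SNPs, zero between blocks, unit diagonal."""
    config.validate()
    n = config.n_snps
    idx = np.arange(n)
    block = idx // config.ld_block_size
    same_block = block[:, None] == block[None, :]
    r2 = np.where(same_block, config.ld_within_block_r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    ids = tuple(f"rs{i + 1}" for i in range(n))
    pos = tuple(int(p) for p in _positions(config))
    return LDMatrix(snp_ids=ids, r2=r2, pos=pos, chrom=tuple(["1"] * n))


def _records(ids, pos, ea, oa, eaf, beta, se, n) -> list[SNPAssociation]:
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, np.nextafter(0.0, 1.0), 1.0)
    return [
        SNPAssociation(
            snp_id=ids[j], chrom="1", pos=int(pos[j]),
            effect_allele=ea[j], other_allele=oa[j],
            beta=float(beta[j]), se=float(se[j]), pval=float(pval[j]),
            eaf=float(eaf[j]), n=int(n),
        )
        for j in range(len(ids))
    ]


def _swap_orientation(recs, swap_mask) -> list[SNPAssociation]:
    out = []
    for rec, swap in zip(recs, swap_mask):
        if swap:
            out.append(
                SNPAssociation(
                    snp_id=rec.snp_id, chrom=rec.chrom, pos=rec.pos,
                    effect_allele=rec.other_allele, other_allele=rec.effect_allele,
                    beta=-rec.beta, se=rec.se, pval=rec.pval,
                    eaf=1.0 - rec.eaf, n=rec.n,
                )
            )
        else:
            out.append(rec)
    return out


def simulate_triplet(config: SimulationConfig) -> SimulatedTriplet:
    """Draw one exposure/mediator/outcome triplet of summary statistics.

    One seeded :class:`numpy.random.Generator` drives every draw in a fixed
    order (maf, alleles, gamma, alpha, outlier placement, per-study noise,
    orientation swaps), so equal configs give bitwise-identical triplets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    maf = rng.uniform(config.maf_low, config.maf_high, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    # true effects; gamma oriented to the exposure-increasing allele
    gamma = np.abs(rng.normal(0.0, math.sqrt(config.instrument_strength), size=n))
    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n)

    outlier_idx = rng.choice(n, size=config.n_outlier_snps, replace=False)
    outlier = np.zeros(n)
    outlier[outlier_idx] = config.outlier_effect

    total = config.beta_exp_med * config.beta_med_out + config.beta_exp_out_direct
    true_exp = gamma
    true_med = gamma * config.beta_exp_med + alpha
    true_out = gamma * total + alpha * config.beta_med_out + outlier

    def _se(n_study):
        return 1.0 / np.sqrt(2.0 * n_study * maf * (1.0 - maf))

    se_exp = _se(config.n_exposure)
    se_med = _se(config.n_mediator)
    se_out = _se(config.n_outcome)

    obs_exp = true_exp + rng.normal(0.0, se_exp)
    obs_med = true_med + rng.normal(0.0, se_med)
    obs_out = true_out + rng.normal(0.0, se_out)

    ld = simulate_ld_blocks(config)
    ids, pos = ld.snp_ids, ld.pos

    exposure = _records(ids, pos, ea, oa, maf, obs_exp, se_exp, config.n_exposure)
    mediator = _records(ids, pos, ea, oa, maf, obs_med, se_med, config.n_mediator)
    outcome = _records(ids, pos, ea, oa, maf, obs_out, se_out, config.n_outcome)

    swap_med = rng.random(n) < config.swap_fraction
    swap_out = rng.random(n) < config.swap_fraction
    mediator = _swap_orientation(mediator, swap_med)
    outcome = _swap_orientation(outcome, swap_out)

    truth = Truth(
        total=total,
        indirect=config.beta_exp_med * config.beta_med_out,
        direct=config.beta_exp_out_direct,
        step1=config.beta_exp_med,
        step2=config.beta_med_out,
        outlier_snp_ids=tuple(ids[i] for i in sorted(outlier_idx)),
        gamma=gamma,
        alpha=alpha,
    )
    return SimulatedTriplet(
        exposure=exposure, mediator=mediator, outcome=outcome,
        ld=ld, truth=truth, config=config,
    )
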