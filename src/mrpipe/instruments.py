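"""Instrument selection and harmonization for two-sample MR.

Selection follows the conventional microbiome-GWAS pipeline: keep SNPs
associated with the exposure at p <= 5e-5 (inclusive threshold), greedily
LD-clump at r² = 0.001 within a 10,000 kb window around each index SNP,
and screen instrument strength with per-SNP F = (beta/se)² summarised by
the mean (mean F > 10 = strong).

Harmonization aligns outcome effects to the exposure's effect allele,
negating the outcome beta where the allele pair is reported in swapped
orientation, resolving strand flips via base complements, and dropping
palindromic (A/T, G/C) SNPs whose orientation cannot be inferred from the
effect-allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .gwas_io import LDMatrix, SNPAssociation

__all__ = [
    "InstrumentConfig",
    "HarmonizedSet",
    "FStatReport",
    "select_by_pvalue",
    "clump",
    "compute_f_statistics",
    "harmonize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class InstrumentConfig:
    """Thresholds for instrument selection.

    ``palindromic_eaf_band``: palindromic SNPs with effect-allele frequency
    within 0.5 ± band (or missing eaf) are dropped as ambiguous.
    """

    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    palindromic_eaf_band: float = 0.08

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 <= self.clump_r2 < 1):
            raise ValueError("clump_r2 must lie in [0, 1)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele."""

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    flipped: np.ndarray  # bool: outcome beta was negated
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        self.flipped = np.asarray(self.flipped, dtype=bool)
        k = len(self.snp_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "flipped"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length != {k}")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("standard errors must be strictly positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in keep],
            beta_exp=self.beta_exp[keep],
            se_exp=self.se_exp[keep],
            beta_out=self.beta_out[keep],
            se_out=self.se_out[keep],
            flipped=self.flipped[keep],
            dropped=list(self.dropped),
        )


def select_by_pvalue(
    assocs: Iterable[SNPAssociation], cfg: InstrumentConfig = InstrumentConfig()
) -> list[SNPAssociation]:
    """Records with pval <= threshold, input order preserved (inclusive boundary)."""
    return [a for a in assocs if a.pval <= cfg.p_threshold]


def clump(
    assocs: Sequence[SNPAssociation],
    ld: LDMatrix,
    cfg: InstrumentConfig = InstrumentConfig(),
) -> list[SNPAssociation]:
    """Greedy LD clumping around index SNPs.

    Repeatedly take the unremoved SNP with the smallest p-value (ties:
    smaller genomic coordinate) as index, and remove every other unremoved
    SNP on the same chromosome within ``clump_window_kb`` whose r² with the
    index exceeds ``clump_r2``.  Retained SNPs are returned in genomic
    order.
    """
    missing = [a.snp_id for a in assocs if a.snp_id not in ld.snp_ids]
    if missing:
        raise KeyError(f"SNPs absent from LD matrix: {missing}")

    items = list(assocs)
    active = set(range(len(items)))
    kept: list[int] = []
    window_bp = cfg.clump_window_kb * 1000

    def _order(i: int):
        a = items[i]
        return (a.pval, a.chrom, a.pos, a.snp_id)

    while active:
        idx = min(active, key=_order)
        kept.append(idx)
        active.discard(idx)
        a = items[idx]
        ai = ld.index_of(a.snp_id)
        for j in list(active):
            b = items[j]
            if b.chrom != a.chrom:
                continue
            if abs(b.pos - a.pos) > window_bp:
                continue
            if ld.r2[ai, ld.index_of(b.snp_id)] > cfg.clump_r2:
                active.discard(j)

    kept_items = [items[i] for i in kept]
    kept_items.sort(key=lambda r: (r.chrom, r.pos, r.snp_id))
    return kept_items


@dataclass(frozen=True)
class FStatReport:
    f_per_snp: np.ndarray
    mean_f: float
    strong: bool


def compute_f_statistics(
    assocs: Sequence[SNPAssociation], cfg: InstrumentConfig = InstrumentConfig()
) -> FStatReport:
    """Per-SNP F = (beta/se)²; instruments are 'strong' iff mean F > f_min."""
    if not assocs:
        raise ValueError("no instruments to assess")
    f = np.array([(a.beta / a.se) ** 2 for a in assocs])
    mean_f = float(f.mean())
    return FStatReport(f_per_snp=f, mean_f=mean_f, strong=mean_f > cfg.f_min)


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT.get(ea) == oa


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def harmonize(
    exposure: Sequence[SNPAssociation],
    outcome: Iterable[SNPAssociation],
    cfg: InstrumentConfig = InstrumentConfig(),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    For each exposure SNP found in the outcome: same allele pair in the
    same orientation is copied; the swapped orientation negates the
    outcome beta (eaf mirrored); strand-complemented pairs are complemented
    first; palindromic SNPs whose eaf is missing or within the ambiguity
    band are dropped; irreconcilable allele pairs are dropped.  Raises if
    no SNP survives.
    """
    out_by_id = {a.snp_id: a for a in outcome}
    band_lo = 0.5 - cfg.palindromic_eaf_band
    band_hi = 0.5 + cfg.palindromic_eaf_band

    ids: list[str] = []
    be, se_e, bo, se_o, flip = [], [], [], [], []
    dropped: list[tuple[str, str]] = []

    for ex in exposure:
        o = out_by_id.get(ex.snp_id)
        if o is None:
            dropped.append((ex.snp_id, "missing-in-outcome"))
            continue

        if _is_palindromic(ex.effect_allele, ex.other_allele):
            ambiguous = (
                ex.eaf is None or o.eaf is None
                or band_lo <= ex.eaf <= band_hi
                or band_lo <= o.eaf <= band_hi
            )
            if ambiguous:
                dropped.append((ex.snp_id, "palindromic-ambiguous"))
                continue
            # orientation inferred from eaf agreement: if the minor allele
            # disagrees between studies the outcome is on the other strand
            # orientation, which for a palindromic SNP flips the sign.
            same_orientation = (ex.eaf < 0.5) == (o.eaf < 0.5)
            beta_out = o.beta if same_orientation else -o.beta
            ids.append(ex.snp_id)
            be.append(ex.beta); se_e.append(ex.se)
            bo.append(beta_out); se_o.append(o.se)
            flip.append(not same_orientation)
            continue

        o_ea, o_oa = o.effect_allele, o.other_allele
        if (o_ea, o_oa) == (ex.effect_allele, ex.other_allele):
            beta_out, flipped = o.beta, False
        elif (o_oa, o_ea) == (ex.effect_allele, ex.other_allele):
            beta_out, flipped = -o.beta, True
        else:
            c_ea, c_oa = _complement(o_ea), _complement(o_oa)
            if (c_ea, c_oa) == (ex.effect_allele, ex.other_allele):
                beta_out, flipped = o.beta, False
            elif (c_oa, c_ea) == (ex.effect_allele, ex.other_allele):
                beta_out, flipped = -o.beta, True
            else:
                dropped.append((ex.snp_id, "allele-mismatch"))
                continue
        ids.append(ex.snp_id)
        be.append(ex.beta); se_e.append(ex.se)
        bo.append(beta_out); se_o.append(o.se)
        flip.append(flipped)

    if not ids:
        raise ValueError("no usable instruments after harmonization")

    return HarmonizedSet(
        snp_ids=ids,
        beta_exp=np.array(be), se_exp=np.array(se_e),
        beta_out=np.array(bo), se_out=np.array(se_o),
        flipped=np.array(flip, dtype=bool),
        dropped=dropped,
    )
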