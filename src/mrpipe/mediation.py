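"""Two-step MR orchestration and effect decomposition.

The two-step design estimates, on the log-odds scale,

    total    = IVW(exposure -> outcome)
    step1    = IVW(exposure -> mediator)
    step2    = IVW(mediator -> outcome), using the mediator's own
               instruments after excluding every SNP used in step 1

and decomposes

    indirect = step1 * step2
    direct   = total - indirect
    proportion mediated = indirect / total        (undefined at total = 0)

Proportions may be negative or exceed 1 when direct and indirect effects
oppose; they are reported as signed values without clipping.  Percent
renderings are exactly 100x the log-scale fields.  The indirect-effect SE
uses the first-order delta method for independent samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .estimators import MRResult, PleiotropyResult, egger, ivw, weighted_median
from .gwas_io import LDMatrix, SNPAssociation, attach_positions
from .instruments import (
    InstrumentConfig,
    clump,
    compute_f_statistics,
    harmonize,
    select_by_pvalue,
)
from .sensitivity import HeterogeneityResult, cochran_q, select_model

__all__ = ["MediationResult", "StageResult", "decompose", "delta_se_indirect", "run_two_step"]


@dataclass(frozen=True)
class MediationResult:
    """Effect decomposition of a two-step MR analysis (log-OR scale).

    Invariants hold bit-for-bit: ``indirect == step1 * step2``,
    ``direct == total - indirect`` and ``proportion * total == indirect``
    whenever ``total != 0``.
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    total: float
    step1: float
    step2: float
    indirect: float
    direct: float
    proportion: float | None  # None when total == 0
    se_indirect: float | None = None

    @property
    def total_pct(self) -> float:
        return 100.0 * self.total

    @property
    def indirect_pct(self) -> float:
        return 100.0 * self.indirect

    @property
    def direct_pct(self) -> float:
        return 100.0 * self.direct

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion


def decompose(
    total: float, step1: float, step2: float,
    exposure_id: str = "exposure", mediator_id: str = "mediator",
    outcome_id: str = "outcome", se_indirect: float | None = None,
) -> MediationResult:
    """Product-of-coefficients decomposition of a total effect."""
    for name, v in (("total", total), ("step1", step1), ("step2", step2)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite {name}={v}")
    indirect = step1 * step2
    direct = total - indirect
    proportion = None if total == 0.0 else indirect / total
    return MediationResult(
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        total=total, step1=step1, step2=step2,
        indirect=indirect, direct=direct, proportion=proportion,
        se_indirect=se_indirect,
    )


def delta_se_indirect(step1: float, se1: float, step2: float, se2: float) -> float:
    """First-order delta-method SE of step1*step2 for independent samples."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    return math.sqrt(step1**2 * se2**2 + step2**2 * se1**2)


@dataclass
class StageResult:
    """One exposure→outcome MR stage with its diagnostics."""

    name: str
    snp_ids: list[str]
    mean_f: float
    ivw: MRResult
    heterogeneity: HeterogeneityResult
    heterogeneity_egger: HeterogeneityResult | None = None
    egger: MRResult | None = None
    pleiotropy: PleiotropyResult | None = None
    weighted_median: MRResult | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)


def _run_stage(
    name: str,
    exposure: Sequence[SNPAssociation],
    outcome: Sequence[SNPAssociation],
    ld: LDMatrix,
    cfg: InstrumentConfig,
    exclude_ids: frozenset[str] = frozenset(),
    n_boot: int = 1000,
    seed: int = 0,
) -> StageResult:
    """Full single-pair pipeline: select, clump, F screen, harmonize, estimate."""
    selected = select_by_pvalue(exposure, cfg)
    selected = [a for a in selected if a.snp_id not in exclude_ids]
    if not selected:
        raise ValueError(f"stage {name!r}: zero instruments after p-value selection")
    ld = attach_positions(ld, selected)
    clumped = clump(selected, ld, cfg)
    fstat = compute_f_statistics(clumped, cfg)
    h = harmonize(clumped, outcome, cfg)

    q = cochran_q(h, "IVW") if h.n_snp >= 2 else None
    model = select_model(q) if q is not None else "n/a"
    res_ivw = ivw(h, model=model if h.n_snp >= 2 else "fixed")
    res_egger = pleio = res_wm = q_egger = None
    if h.n_snp >= 3:
        res_egger, pleio = egger(h)
        res_wm = weighted_median(h, n_boot=n_boot, seed=seed)
        q_egger = cochran_q(h, "Egger")
    if q is None:
        q = HeterogeneityResult(method="IVW", q=0.0, df=1, pval=1.0)
    return StageResult(
        name=name, snp_ids=list(h.snp_ids), mean_f=fstat.mean_f,
        ivw=res_ivw, heterogeneity=q, heterogeneity_egger=q_egger,
        egger=res_egger, pleiotropy=pleio,
        weighted_median=res_wm, dropped=h.dropped,
    )


@dataclass
class TwoStepResult:
    mediation: MediationResult
    total_stage: StageResult
    step1_stage: StageResult
    step2_stage: StageResult


def run_two_step(
    exposure: Sequence[SNPAssociation],
    mediator: Sequence[SNPAssociation],
    outcome: Sequence[SNPAssociation],
    ld_exposure: LDMatrix,
    ld_mediator: LDMatrix,
    cfg: InstrumentConfig = InstrumentConfig(),
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    n_boot: int = 1000,
    seed: int = 0,
) -> TwoStepResult:
    """Two-step MR: total, step-1 and step-2 IVW estimates plus decomposition.

    Step 2 uses the mediator's own instruments with every step-1 SNP id
    excluded, so the two instrument sets are disjoint by construction.
    """
    total_stage = _run_stage("total", exposure, outcome, ld_exposure, cfg,
                             n_boot=n_boot, seed=seed)
    step1_stage = _run_stage("step1", exposure, mediator, ld_exposure, cfg,
                             n_boot=n_boot, seed=seed)
    step2_stage = _run_stage(
        "step2", mediator, outcome, ld_mediator, cfg,
        exclude_ids=frozenset(step1_stage.snp_ids), n_boot=n_boot, seed=seed,
    )
    med = decompose(
        total=total_stage.ivw.beta,
        step1=step1_stage.ivw.beta,
        step2=step2_stage.ivw.beta,
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        se_indirect=delta_se_indirect(
            step1_stage.ivw.beta, step1_stage.ivw.se,
            step2_stage.ivw.beta, step2_stage.ivw.se,
        ),
    )
    return TwoStepResult(mediation=med, total_stage=total_stage,
                         step1_stage=step1_stage, step2_stage=step2_stage)
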