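"""Bundled worked example: effect decomposition from published odds ratios.

A two-step MR study of skin microbiota (exposures), circulating metabolic
biomarkers (mediators, GWAS Catalog accessions GCST903…) and epilepsy
(outcome) reports its univariate and two-step results as odds ratios.
Those printed ORs, transcribed here as data, are sufficient to reproduce
the study's effect-decomposition table at the desk: on the log-odds scale
``total = ln(OR_univariate)``, ``step1``/``step2`` are the logs of the
two-step ORs, and the product-of-coefficients decomposition gives the
indirect/direct effects and the proportion mediated, conventionally
rendered as percentages (``ln(OR) × 100``).

Because the source table prints ORs to four decimals, effects recomputed
from them can differ from the study's own unrounded intermediates by up
to the rounding half-width; see docs/methods.md.
"""

from __future__ import annotations

import math

import pandas as pd

from .mediation import MediationResult, decompose

__all__ = ["UNIVARIATE_OR", "STEP1_OR", "STEP2_OR", "MEDIATION_PAIRS", "reproduce_tables"]

#: Univariate (exposure -> outcome) odds ratios: exposure -> (p, OR).
UNIVARIATE_OR: dict[str, tuple[float, float]] = {
    "asv008": (0.0114, 0.9899),
    "asv022": (0.0083, 0.9886),
    "asv039": (0.0081, 1.0101),
    "asv042": (0.0420, 0.9924),
    "bacillales": (0.0195, 1.0119),
    "clostridiales": (0.0428, 1.0102),
    "micrococcaceae": (0.0397, 1.0111),
    "neisseriaceae": (0.0291, 1.0133),
    "staphylococcus": (0.0287, 1.0106),
}

#: Step-1 (exposure -> mediator) odds ratios: (exposure, mediator) -> (p, OR).
STEP1_OR: dict[tuple[str, str], tuple[float, float]] = {
    ("asv008", "GCST90302078"): (0.0294, 1.0003),
    ("asv022", "GCST90301994"): (0.0011, 0.9960),
    ("bacillales", "GCST90302151"): (0.0316, 0.9932),
    ("clostridiales", "GCST90302078"): (0.0381, 0.9969),
    ("micrococcaceae", "GCST90301965"): (0.0291, 0.9963),
}

#: Step-2 (mediator -> outcome) odds ratios: mediator -> (p, OR).
STEP2_OR: dict[str, tuple[float, float]] = {
    "GCST90301965": (0.0372, 1.0655),  # glutamine level
    "GCST90301994": (0.0487, 1.0675),  # leucine level
    "GCST90302078": (0.0309, 0.9017),  # ratio of saturated fatty acids
    "GCST90302151": (0.0302, 0.9308),  # phospholipids in medium LDL
}

#: Exposure/mediator pairs of the decomposition table, in printed order.
MEDIATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("asv022", "GCST90301994"),
    ("bacillales", "GCST90302151"),
    ("asv008", "GCST90302078"),
    ("clostridiales", "GCST90302078"),
    ("micrococcaceae", "GCST90301965"),
)

OUTCOME_ID = "epilepsy"


def decompose_pair(exposure: str, mediator: str) -> MediationResult:
    """Decomposition for one exposure/mediator pair from the printed ORs."""
    total = math.log(UNIVARIATE_OR[exposure][1])
    step1 = math.log(STEP1_OR[(exposure, mediator)][1])
    step2 = math.log(STEP2_OR[mediator][1])
    return decompose(total, step1, step2, exposure_id=exposure,
                     mediator_id=mediator, outcome_id=OUTCOME_ID)


def reproduce_tables(rounded: bool = True) -> pd.DataFrame:
    """Effect-decomposition table recomputed from the bundled printed ORs.

    One row per exposure/mediator pair with total, indirect and direct
    effects as percentages (``ln(OR) × 100``) and the mediator percentage
    (indirect/total × 100).  With ``rounded=True`` effects are rendered to
    three decimals and the mediator percentage to two, the table's printed
    precision; ``rounded=False`` keeps full precision.
    """
    rows = []
    for exposure, mediator in MEDIATION_PAIRS:
        m = decompose_pair(exposure, mediator)
        row = {
            "exposure": exposure,
            "mediator": mediator,
            "outcome": OUTCOME_ID,
            "total_pct": m.total_pct,
            "indirect_pct": m.indirect_pct,
            "direct_pct": m.direct_pct,
            "mediator_pct": m.proportion_pct,
        }
        if rounded:
            row["total_pct"] = round(row["total_pct"], 3)
            row["indirect_pct"] = round(row["indirect_pct"], 3)
            row["direct_pct"] = round(row["direct_pct"], 3)
            row["mediator_pct"] = round(row["mediator_pct"], 2)
        rows.append(row)
    return pd.DataFrame(rows)
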