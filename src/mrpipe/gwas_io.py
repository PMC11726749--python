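"""Reading, validating and writing GWAS summary statistics and LD matrices.

Summary statistics travel as tab-separated text with one row per SNP.  The
canonical header is ``snp_id  chrom  pos  effect_allele  other_allele  eaf
beta  se  pval  n``; named dialects map common alternative column layouts
onto it.  Validation is strict but never silent: every rejected row is
reported with its line number and reason, and
``len(read rows) == len(accepted) + len(rejected)`` always holds.

Coordinates are 1-based base pairs; alleles are uppercased on ingest.
Effect-allele frequency (``eaf``) and sample size (``n``) may be missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNPAssociation",
    "LDMatrix",
    "ValidationReport",
    "FormatError",
    "DIALECTS",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
]

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Named column dialects for common summary-statistic export layouts.
#: Keys are canonical column names, values the column name found in the file.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    # GWAS-Catalog-style harmonised export headers
    "gwas_catalog": {
        "snp_id": "variant_id",
        "chrom": "chromosome",
        "pos": "base_pair_location",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "effect_allele_frequency",
        "beta": "beta",
        "se": "standard_error",
        "pval": "p_value",
        "n": "n",
    },
    # FinnGen-style release headers
    "finngen": {
        "snp_id": "rsids",
        "chrom": "#chrom",
        "pos": "pos",
        "effect_allele": "alt",
        "other_allele": "ref",
        "eaf": "af_alt",
        "beta": "beta",
        "se": "sebeta",
        "pval": "pval",
        "n": "n",
    },
    # short-hand headers (b / p variants) seen in plink-era exports
    "terse": {
        "snp_id": "snp",
        "chrom": "chr",
        "pos": "bp",
        "effect_allele": "a1",
        "other_allele": "a2",
        "eaf": "freq",
        "beta": "b",
        "se": "se",
        "pval": "p",
        "n": "n",
    },
}

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file-level problem: missing column, non-square LD matrix, bad header."""


@dataclass(frozen=True)
class SNPAssociation:
    """One SNP's summary-statistic record for one trait.

    ``beta`` is the per-effect-allele effect on the trait (log-odds for a
    binary outcome, standardized units otherwise), ``se`` its standard
    error and ``pval`` the association p-value.  ``eaf``/``n`` are optional.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> None:
        if not self.snp_id:
            raise ValueError("empty snp_id")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        for name, allele in (("effect_allele", self.effect_allele),
                             ("other_allele", self.other_allele)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} {allele!r} not over A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect_allele equals other_allele")
        if not math.isfinite(self.beta):
            raise ValueError(f"non-finite beta {self.beta}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be positive, got {self.se}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"pval {self.pval} outside (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"eaf {self.eaf} outside [0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise r² between SNPs, with per-SNP base-pair positions."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray
    pos: tuple[int, ...]
    chrom: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if r2.shape != (k, k):
            raise FormatError(f"LD matrix shape {r2.shape} does not match {k} SNP ids")
        if len(self.pos) != k:
            raise FormatError("positions length does not match SNP ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise FormatError("LD matrix asymmetric beyond 1e-8")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise FormatError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1.0 + 1e-12:
            raise FormatError("LD r2 entries must lie in [0, 1]")
        object.__setattr__(self, "r2", r2)

    def index_of(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(snp_id) from None


@dataclass
class ValidationReport:
    """Per-row accounting of an ingest: accepted count plus rejects."""

    n_rows: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)

    @property
    def n_accepted(self) -> int:
        return self.n_rows - len(self.rejects)

    def summary(self) -> str:
        lines = [f"{self.n_accepted}/{self.n_rows} rows accepted"]
        lines += [f"  line {ln}: {why}" for ln, why in self.rejects]
        return "\n".join(lines)


def _coerce_record(row: pd.Series, line_no: int) -> SNPAssociation:
    def _opt_float(v):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "" or pd.isna(v):
            return None
        return float(v)

    eaf = _opt_float(row["eaf"])
    n_raw = _opt_float(row["n"])
    try:
        rec = SNPAssociation(
            snp_id=str(row["snp_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            eaf=eaf,
            n=int(round(n_raw)) if n_raw is not None else None,
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparseable value ({exc})") from exc
    rec.validate()
    return rec


def read_summary_stats(
    path,
    dialect: str | Mapping[str, str] = "canonical",
    sep: str = "\t",
) -> tuple[list[SNPAssociation], ValidationReport]:
    """Read summary statistics from delimited text.

    ``dialect`` is either the name of a preset in :data:`DIALECTS` or a
    mapping from canonical column names to the file's column names.
    Returns the accepted records in input row order together with a
    :class:`ValidationReport` listing every rejected row.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    missing_map = set(CANONICAL_COLUMNS) - set(mapping) - {"eaf", "n"}
    if missing_map:
        raise FormatError(f"dialect missing canonical columns: {sorted(missing_map)}")

    df = pd.read_csv(path, sep=sep, dtype=str)
    for canon in CANONICAL_COLUMNS:
        col = mapping.get(canon)
        if canon in ("eaf", "n") and (col is None or col not in df.columns):
            df[canon] = None
            continue
        if col is None or col not in df.columns:
            raise FormatError(f"missing mandatory column {col or canon!r}")
        if col != canon:
            df[canon] = df[col]

    records: list[SNPAssociation] = []
    report = ValidationReport(n_rows=len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        line_no = i + 2  # header is line 1
        try:
            records.append(_coerce_record(row, line_no))
        except ValueError as exc:
            report.rejects.append((line_no, str(exc)))
    return records, report


def write_summary_stats(records: Iterable[SNPAssociation], path) -> None:
    """Write records as canonical tab-separated text.

    Reals are rendered with 17 significant digits so that a
    read→write→read cycle is lossless (well beyond 15 significant digits).
    """
    recs = list(records)
    for r in recs:
        r.validate()

    def _fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        r.snp_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
                        r.eaf, r.beta, r.se, r.pval, r.n,
                    )
                )
                + "\n"
            )


def read_ld_matrix(path, sep: str = "\t") -> LDMatrix:
    """Read a labelled square r² matrix.

    Expected layout: header row of SNP ids (first cell blank or ``snp_id``),
    one labelled row per SNP.  Positions are not stored in the matrix file;
    they default to 0 and are normally supplied by the caller from the
    summary statistics (see :func:`attach_positions`).
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"LD matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise FormatError("LD matrix row labels do not match column labels")
    ids = tuple(str(s) for s in df.columns)
    return LDMatrix(snp_ids=ids, r2=df.to_numpy(dtype=float), pos=tuple([0] * len(ids)))


def write_ld_matrix(ld: LDMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(ld.r2, index=list(ld.snp_ids), columns=list(ld.snp_ids))
    df.to_csv(path, sep=sep, float_format="%.17g")


def attach_positions(ld: LDMatrix, assocs: Sequence[SNPAssociation]) -> LDMatrix:
    """Return a copy of ``ld`` with positions/chromosomes taken from records."""
    by_id = {a.snp_id: a for a in assocs}
    pos, chrom = [], []
    for s in ld.snp_ids:
        a = by_id.get(s)
        pos.append(a.pos if a else 0)
        chrom.append(a.chrom if a else "")
    return replace(ld, pos=tuple(pos), chrom=tuple(chrom))
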