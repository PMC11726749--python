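"""End-to-end screening pipelines and report generation.

`run_univariate_screen` runs the full single-pair pipeline (p-value
selection, LD clumping, F screen, harmonization, IVW with heterogeneity-
driven model selection, MR-Egger, weighted median, Cochran's Q, Egger
intercept, MR-PRESSO) for every exposure file against one outcome, and
writes a per-exposure×method report plus a filtered view of exposures
passing the IVW reporting threshold.

`run_two_step_screen` additionally runs every exposure×mediator pair
through the two-step mediation analysis and writes five tab-separated
report tables: univariate results, two-step step-1/step-2 results,
heterogeneity, pleiotropy intercepts, and the effect decomposition.

Reports are deterministic for a fixed config: every table carries the
seed and a sha256 config hash, no timestamps are embedded, and floats are
rendered with a fixed format, so identical runs are byte-identical.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gwas_io import LDMatrix, SNPAssociation, read_ld_matrix, read_summary_stats, write_ld_matrix, write_summary_stats
from .instruments import InstrumentConfig
from .mediation import StageResult, _run_stage, run_two_step
from .sensitivity import MRPresso
from .simulate import SimulationConfig, simulate_triplet
from .worked_example import reproduce_tables

__all__ = ["RunConfig", "run_univariate_screen", "run_two_step_screen", "run_simulate", "reproduce_paper_tables"]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run (YAML-loadable)."""

    mode: str = "univariate"  # univariate | two-step | simulate
    exposure: list[str] = field(default_factory=list)  # file paths or globs
    mediator: list[str] = field(default_factory=list)
    outcome: str | None = None
    ld: str | None = None  # optional LD matrix path; identity if absent
    dialect: str = "canonical"
    instruments: InstrumentConfig = field(default_factory=InstrumentConfig)
    simulate: SimulationConfig | None = None
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    p_report: float = 0.05
    out_dir: str = "mr_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inst = InstrumentConfig(**raw.pop("instruments", {}))
        sim_raw = raw.pop("simulate", None)
        sim = SimulationConfig(**sim_raw) if sim_raw is not None else None
        exposure = raw.pop("exposure", [])
        if isinstance(exposure, str):
            exposure = [exposure]
        mediator = raw.pop("mediator", [])
        if isinstance(mediator, str):
            mediator = [mediator]
        return cls(exposure=exposure, mediator=mediator, instruments=inst,
                   simulate=sim, **raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _expand(patterns: list[str]) -> list[str]:
    paths: list[str] = []
    for pat in patterns:
        hits = sorted(_glob.glob(pat))
        paths.extend(hits if hits else ([pat] if os.path.exists(pat) else []))
    return paths


def _identity_ld(assocs: list[SNPAssociation]) -> LDMatrix:
    ids = tuple(a.snp_id for a in assocs)
    return LDMatrix(snp_ids=ids, r2=np.eye(len(ids)), pos=tuple(a.pos for a in assocs),
                    chrom=tuple(a.chrom for a in assocs))


def _load(path: str, dialect: str) -> list[SNPAssociation]:
    records, _report = read_summary_stats(path, dialect=dialect)
    return records


def _ld_for(cfg: RunConfig, assocs: list[SNPAssociation]) -> LDMatrix:
    if cfg.ld is None:
        return _identity_ld(assocs)
    return read_ld_matrix(cfg.ld)


def _trait_name(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]


def _method_rows(name: str, outcome_name: str, stage: StageResult,
                 cfg: RunConfig) -> list[dict]:
    rows = []
    results = [stage.ivw]
    if stage.egger is not None:
        results.append(stage.egger)
    if stage.weighted_median is not None:
        results.append(stage.weighted_median)
    for r in results:
        rows.append({
            "exposure": name, "outcome": outcome_name,
            "method": r.method, "model": r.model, "n_snp": r.n_snp,
            "pval": r.pval, "or": round(r.or_, 4),
            "ci_low": round(r.ci_low, 4), "ci_high": round(r.ci_high, 4),
            "mean_f": round(stage.mean_f, 2),
            "seed": cfg.seed, "config_hash": cfg.config_hash(),
        })
    return rows


def _het_pleio_rows(name: str, outcome_name: str, stage: StageResult):
    het = [{
        "exposure": name, "outcome": outcome_name, "method": "IVW",
        "q": stage.heterogeneity.q, "df": stage.heterogeneity.df,
        "q_pval": stage.heterogeneity.pval,
    }]
    pleio = []
    if stage.heterogeneity_egger is not None:
        het.append({
            "exposure": name, "outcome": outcome_name, "method": "Egger",
            "q": stage.heterogeneity_egger.q,
            "df": stage.heterogeneity_egger.df,
            "q_pval": stage.heterogeneity_egger.pval,
        })
    if stage.pleiotropy is not None:
        pleio.append({
            "exposure": name, "outcome": outcome_name,
            "intercept": round(stage.pleiotropy.intercept, 4),
            "se": round(stage.pleiotropy.se, 4),
            "pval": round(stage.pleiotropy.pval, 4),
        })
    return het, pleio


def _presso_row(name: str, outcome_name: str, stage_ids, exposure, outcome,
                cfg: RunConfig) -> dict | None:
    """MR-PRESSO on the stage's instrument set (requires >= 4 instruments)."""
    ids = set(stage_ids)
    exp = [a for a in exposure if a.snp_id in ids]
    from .instruments import harmonize
    try:
        h = harmonize(exp, outcome, cfg.instruments)
        det = MRPresso(n_sim=cfg.n_sim, n_boot=cfg.n_boot,
                       random_state=cfg.seed).fit(
            h.beta_exp[:, None], h.beta_out, sample_weight=1.0 / h.se_out**2)
    except ValueError:
        return None
    return {
        "exposure": name, "outcome": outcome_name,
        "rss_obs": det.rss_obs_, "global_pval": det.global_pval_,
        "n_outliers": int(det.outlier_mask_.sum()),
        "outlier_snps": ",".join(np.array(h.snp_ids)[det.outlier_mask_]),
        "distortion_pval": det.distortion_pval_,
    }


def _write(df: pd.DataFrame, out_dir: str, name: str) -> None:
    df.to_csv(os.path.join(out_dir, name), sep="\t", index=False,
              float_format=_FLOAT_FMT)


def _write_metadata(cfg: RunConfig, out_dir: str, extra: dict | None = None) -> None:
    meta = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
            "version": __version__}
    if extra:
        meta.update(extra)
    with open(os.path.join(out_dir, "run_metadata.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def run_univariate_screen(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Screen every exposure file against the outcome; see module docstring."""
    exp_paths = _expand(cfg.exposure)
    if not exp_paths:
        raise FileNotFoundError(f"no exposure files match {cfg.exposure}")
    if cfg.outcome is None:
        raise ValueError("outcome file required")
    outcome = _load(cfg.outcome, cfg.dialect)
    outcome_name = _trait_name(cfg.outcome)

    rows, het_rows, pleio_rows, presso_rows, skipped = [], [], [], [], []
    for path in exp_paths:
        name = _trait_name(path)
        exposure = _load(path, cfg.dialect)
        try:
            stage = _run_stage(name, exposure, outcome, _ld_for(cfg, exposure),
                               cfg.instruments, n_boot=cfg.n_boot, seed=cfg.seed)
        except ValueError as exc:
            skipped.append({"exposure": name, "reason": str(exc)})
            continue
        rows += _method_rows(name, outcome_name, stage, cfg)
        het, pleio = _het_pleio_rows(name, outcome_name, stage)
        het_rows += het
        pleio_rows += pleio
        pr = _presso_row(name, outcome_name, stage.snp_ids, exposure, outcome, cfg)
        if pr is not None:
            presso_rows.append(pr)

    table1 = pd.DataFrame(rows)
    sig = table1[(table1["method"].isin(["IVW", "WaldRatio"]))
                 & (table1["pval"] <= cfg.p_report)] if len(table1) else table1
    out = {
        "table1_univariate": table1,
        "table1_significant": sig.reset_index(drop=True),
        "table3_heterogeneity": pd.DataFrame(het_rows),
        "table4_pleiotropy": pd.DataFrame(pleio_rows),
        "presso": pd.DataFrame(presso_rows),
        "skipped": pd.DataFrame(skipped),
    }
    os.makedirs(cfg.out_dir, exist_ok=True)
    for name, df in out.items():
        _write(df, cfg.out_dir, f"{name}.tsv")
    _write_metadata(cfg, cfg.out_dir)
    return out


def run_two_step_screen(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Two-step MR over every exposure×mediator pair plus the univariate screen.

    Pairs are retained in the decomposition table only when both the
    step-1 and step-2 IVW p-values pass the reporting threshold; pairs
    with IVW heterogeneity p < 0.05 at any stage are excluded from the
    final table set (recorded in ``skipped``).
    """
    exp_paths = _expand(cfg.exposure)
    med_paths = _expand(cfg.mediator)
    if not exp_paths or not med_paths:
        raise FileNotFoundError("two-step mode needs exposure and mediator files")
    if cfg.outcome is None:
        raise ValueError("outcome file required")
    outcome = _load(cfg.outcome, cfg.dialect)
    outcome_name = _trait_name(cfg.outcome)

    uni = run_univariate_screen(replace(cfg, mediator=[]))

    t2_rows, t3_rows, t4_rows, t5_rows, skipped = [], [], [], [], []
    for ep in exp_paths:
        exposure = _load(ep, cfg.dialect)
        ename = _trait_name(ep)
        for mp in med_paths:
            mediator = _load(mp, cfg.dialect)
            mname = _trait_name(mp)
            try:
                res = run_two_step(
                    exposure, mediator, outcome,
                    _ld_for(cfg, exposure), _ld_for(cfg, mediator),
                    cfg.instruments, exposure_id=ename, mediator_id=mname,
                    outcome_id=outcome_name, n_boot=cfg.n_boot, seed=cfg.seed,
                )
            except ValueError as exc:
                skipped.append({"exposure": ename, "mediator": mname,
                                "reason": str(exc)})
                continue

            stages = (("step1", ename, mname, res.step1_stage),
                      ("step2", mname, outcome_name, res.step2_stage))
            for label, sname, soutname, stage in stages:
                r = stage.ivw
                t2_rows.append({
                    "step": label, "exposure": sname, "outcome": soutname,
                    "pval": r.pval, "or": round(r.or_, 4),
                    "ci_low": round(r.ci_low, 4), "ci_high": round(r.ci_high, 4),
                    "n_snp": r.n_snp, "seed": cfg.seed,
                    "config_hash": cfg.config_hash(),
                })
                t3_rows.append({
                    "step": label, "exposure": sname, "outcome": soutname,
                    "method": "IVW", "q": round(stage.heterogeneity.q, 1),
                    "df": stage.heterogeneity.df,
                    "q_pval": round(stage.heterogeneity.pval, 3),
                })
                if stage.heterogeneity_egger is not None:
                    t3_rows.append({
                        "step": label, "exposure": sname, "outcome": soutname,
                        "method": "Egger",
                        "q": round(stage.heterogeneity_egger.q, 1),
                        "df": stage.heterogeneity_egger.df,
                        "q_pval": round(stage.heterogeneity_egger.pval, 3),
                    })
                if stage.pleiotropy is not None:
                    t4_rows.append({
                        "step": label, "exposure": sname, "outcome": soutname,
                        "intercept": round(stage.pleiotropy.intercept, 4),
                        "se": round(stage.pleiotropy.se, 4),
                        "pval": round(stage.pleiotropy.pval, 4),
                    })

            het_fail = any(
                s.heterogeneity.pval < 0.05
                for s in (res.total_stage, res.step1_stage, res.step2_stage)
            )
            both_sig = (res.step1_stage.ivw.pval <= cfg.p_report
                        and res.step2_stage.ivw.pval <= cfg.p_report)
            if het_fail:
                skipped.append({"exposure": ename, "mediator": mname,
                                "reason": "heterogeneity p < 0.05"})
                continue
            if not both_sig:
                continue
            m = res.mediation
            t5_rows.append({
                "exposure": ename, "mediator": mname, "outcome": outcome_name,
                "total_pct": round(m.total_pct, 3),
                "indirect_pct": round(m.indirect_pct, 3),
                "direct_pct": round(m.direct_pct, 3),
                "mediator_pct": (np.nan if m.proportion_pct is None
                                 else round(m.proportion_pct, 2)),
                "se_indirect": m.se_indirect,
                "seed": cfg.seed, "config_hash": cfg.config_hash(),
            })

    out = {
        "table1_univariate": uni["table1_univariate"],
        "table2_twostep": pd.DataFrame(t2_rows),
        "table3_heterogeneity": pd.DataFrame(t3_rows),
        "table4_pleiotropy": pd.DataFrame(t4_rows),
        "table5_mediation": pd.DataFrame(t5_rows),
        "skipped": pd.DataFrame(skipped),
    }
    os.makedirs(cfg.out_dir, exist_ok=True)
    for name, df in out.items():
        _write(df, cfg.out_dir, f"{name}.tsv")
    _write_metadata(cfg, cfg.out_dir)
    return out


def run_simulate(cfg: RunConfig) -> dict[str, str]:
    """Generate a synthetic triplet and write it via the gwas_io writers."""
    sim = cfg.simulate or SimulationConfig(seed=cfg.seed)
    trip = simulate_triplet(sim)
    os.makedirs(cfg.out_dir, exist_ok=True)
    paths = {}
    for name, recs in (("exposure", trip.exposure), ("mediator", trip.mediator),
                       ("outcome", trip.outcome)):
        p = os.path.join(cfg.out_dir, f"{name}.tsv")
        write_summary_stats(recs, p)
        paths[name] = p
    ldp = os.path.join(cfg.out_dir, "ld.tsv")
    write_ld_matrix(trip.ld, ldp)
    paths["ld"] = ldp
    _write_metadata(cfg, cfg.out_dir, extra={
        "truth": {"total": trip.truth.total, "indirect": trip.truth.indirect,
                  "direct": trip.truth.direct,
                  "outlier_snp_ids": list(trip.truth.outlier_snp_ids)}})
    return paths


def reproduce_paper_tables(out_dir: str | None = None) -> pd.DataFrame:
    """Worked-example decomposition from the bundled printed ORs."""
    df = reproduce_tables(rounded=True)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        _write(df, out_dir, "table5_mediation_worked_example.tsv")
    return df
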