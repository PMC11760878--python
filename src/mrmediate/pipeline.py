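"""End-to-end orchestration of the two-step MR mediation workflow.

Per analysis direction: read → select instruments (significance, clumping,
F-statistic, confounder exclusions) → harmonize with the outcome → drop
outcome-associated instruments → outlier removal → Steiger directionality →
five MR estimators → causal call → sensitivity table.  Then, per
exposure→mediator→outcome triplet: stage-1 exposure→mediator regression,
stage-2 mediator→outcome IVW, and product-of-coefficients mediation.

All randomness derives from one global seed; identical config + seed gives
byte-identical report files.  Every dropped instrument is kept in an audit
table with exactly one drop reason, and kept + dropped always partitions
the input (asserted per direction).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, estimators, instruments, mediation
from .instruments import SelectionConfig
from .simulate import SimulationConfig, make_three_gwas
from .sumstats import HarmonizedTable, SummaryTable, harmonize, read_summary_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML/JSON file or in-memory).

    Either ``exposures``/``mediator``/``outcomes`` map trait names to
    summary-statistic TSV paths, or ``simulation`` holds
    :class:`~mrmediate.simulate.SimulationConfig` keyword arguments.
    """

    seed: int = 0
    exposures: dict[str, str] = field(default_factory=dict)
    mediator: dict[str, str] = field(default_factory=dict)
    outcomes: dict[str, str] = field(default_factory=dict)
    exclusions: dict[str, str] = field(default_factory=dict)  # trait → TSV
    simulation: dict | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    ivw_model: str = "auto"
    phi: float = 1.0
    n_boot: int = 1000
    presso_n_sim: int = 1000
    mediation_mode: str = "summary"  # summary | individual
    palindrome_policy: str = "infer_by_eaf"
    eaf_tolerance: float = 0.08
    alpha: float = 0.05
    outdir: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: malformed config")
        if "selection" in raw:
            raw["selection"] = SelectionConfig(**raw["selection"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Paper-shaped report bundle for one pipeline run."""

    direct_effects: pd.DataFrame      # exposure → outcome, five methods
    stage1: pd.DataFrame              # exposure → mediator coefficients
    mediator_outcome: pd.DataFrame    # mediator → outcome, five methods
    mediation: pd.DataFrame           # Bm/Sm/Z/Pm/CI per triplet
    sensitivity: pd.DataFrame         # Q/Egger/outlier/Steiger per direction
    audit: pd.DataFrame               # every instrument with status + reason
    per_snp: pd.DataFrame             # plot-ready (ratio, se) per direction
    manifest: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "direct_effects.tsv": self.direct_effects,
            "stage1.tsv": self.stage1,
            "mediator_outcome.tsv": self.mediator_outcome,
            "mediation.tsv": self.mediation,
            "sensitivity.tsv": self.sensitivity,
            "audit.tsv": self.audit,
            "per_snp.tsv": self.per_snp,
        }
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False,
                      float_format="%.10g", na_rep="NA")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str)
            + "\n")


def _child_seed(seed: int, *tags: str) -> int:
    """Deterministic sub-seed derived from the global seed and a label."""
    h = np.uint64(seed)
    for tag in tags:
        for ch in tag:
            h = (h * np.uint64(1000003) + np.uint64(ord(ch))) % np.uint64(2**31)
    return int(h)


def _panel_rows(direction: str, panel: estimators.MethodPanel,
                call: estimators.CausalCall) -> list[dict]:
    rows = []
    for name, e in panel.estimates.items():
        rows.append({
            "direction": direction, "method": name, "n_snps": e.n_snps,
            "B": e.B, "S": e.SE, "P": e.pval, "OR": e.OR,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "ivw_model": e.model or "",
            "consistent": panel.directionally_consistent,
            "significant": call.significant, "call": call.direction,
        })
    return rows


def run_direction(exposure: SummaryTable, outcome: SummaryTable,
                  config: PipelineConfig,
                  exclusions: dict[str, str] | None = None,
                  ld=None) -> dict:
    """One exposure→outcome analysis direction.

    Returns a dict with the candidate audit table, stage counts, the final
    harmonized table, the five-method panel + causal call, and the
    sensitivity diagnostics; ``failed`` is set when fewer than two
    instruments survive.
    """
    sel = config.selection
    direction = f"{exposure.trait_id}->{outcome.trait_id}"
    cand = instruments.select_by_pvalue(exposure, sel.p_threshold)
    counts = {"input": len(cand)}
    cand = instruments.clump(cand, sel.clump_r2, sel.clump_window_kb, ld)
    cand = instruments.filter_weak(cand, sel.f_min)
    cand = instruments.apply_exclusions(cand, exclusions or {})

    kept = instruments.kept_ids(cand)
    ex_sel = SummaryTable(exposure.trait_id, exposure.trait_type,
                          exposure.df[exposure.df["variant_id"].isin(kept)]
                          .reset_index(drop=True))
    result: dict = {"direction": direction, "failed": False}
    h = None
    if len(ex_sel) > 0 and len(outcome.df) > 0:
        try:
            h = harmonize(ex_sel, outcome, config.palindrome_policy,
                          config.eaf_tolerance)
        except ValueError:
            h = None
    if h is not None:
        present = set(h.df["variant_id"])
        missing = (cand["status"] == "kept") & ~cand["variant_id"].isin(present)
        cand.loc[missing, "status"] = "dropped"
        cand.loc[missing, "drop_reason"] = "missing_in_outcome"
        h, removed = instruments.filter_outcome_associated(
            h, sel.outcome_p_exclude)
        hit = cand["variant_id"].isin(removed)
        cand.loc[hit, "status"] = "dropped"
        cand.loc[hit, "drop_reason"] = "outcome_associated"

    presso = None
    if h is not None and len(h) >= 4:
        presso = diagnostics.mr_presso(
            h, n_sim=config.presso_n_sim,
            seed=_child_seed(config.seed, "presso", direction))
        if presso.outlier_ids:
            out_hit = cand["variant_id"].isin(presso.outlier_ids)
            cand.loc[out_hit, "status"] = "dropped"
            cand.loc[out_hit, "drop_reason"] = "presso_outlier"
            h = h.subset(~h.df["variant_id"].isin(presso.outlier_ids))

    # stage-count conservation: kept + every drop reason partitions input
    by_reason = cand.loc[cand["status"] == "dropped", "drop_reason"] \
        .value_counts().to_dict()
    counts.update({"kept": int((cand["status"] == "kept").sum()), **by_reason})
    assert counts["input"] == counts["kept"] + sum(by_reason.values())

    cand.insert(0, "direction", direction)
    result.update({"candidates": cand, "counts": counts, "harmonized": h})

    if h is None or len(h) < 2:
        result["failed"] = True
        return result

    panel = estimators.method_panel(
        h, model=config.ivw_model, phi=config.phi, n_boot=config.n_boot,
        seed=_child_seed(config.seed, "panel", direction))
    call = estimators.causal_call(panel, alpha=config.alpha)
    het = diagnostics.cochran_q(h, panel.estimates["ivw"].B
                                if panel.estimates["ivw"].model == "fixed"
                                else None)
    pleio = diagnostics.egger_intercept_test(h) if len(h) >= 3 else None
    try:
        stg = diagnostics.steiger(h)
    except ValueError:
        stg = None
    sens = {
        "direction": direction, "n_snps": len(h),
        "Q": het.Q, "Q_df": het.df, "Q_pval": het.pval,
        "egger_intercept": pleio.intercept if pleio else np.nan,
        "egger_intercept_se": pleio.se if pleio else np.nan,
        "egger_intercept_pval": pleio.pval if pleio else np.nan,
        "presso_global_pval": presso.global_pval if presso else np.nan,
        "n_presso_outliers": len(presso.outlier_ids) if presso else 0,
        "steiger_correct": stg.correct_direction if stg else np.nan,
        "steiger_pval": stg.pval if stg else np.nan,
        "steiger_r2_exposure": stg.r2_exposure if stg else np.nan,
        "steiger_r2_outcome": stg.r2_outcome if stg else np.nan,
    }
    r, rse = estimators.wald_ratios(h)
    per_snp = pd.DataFrame({
        "direction": direction,
        "variant_id": h.df.loc[h.df["beta_x"] != 0, "variant_id"].to_numpy(),
        "ratio": r, "ratio_se": rse,
    })
    result.update({"panel": panel, "call": call, "sensitivity": sens,
                   "per_snp": per_snp})
    return result


def _load_tables(config: PipelineConfig):
    if config.simulation is not None:
        sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
        ex, med, out, truth = make_three_gwas(sim)
        return {"exposure": ex}, {"mediator": med}, {"outcome": out}, truth
    exposures = {name: read_summary_table(p, trait_id=name)
                 for name, p in config.exposures.items()}
    mediators = {name: read_summary_table(p, trait_id=name)
                 for name, p in config.mediator.items()}
    outcomes = {name: read_summary_table(p, trait_id=name, trait_type="binary")
                for name, p in config.outcomes.items()}
    return exposures, mediators, outcomes, None


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full workflow and assemble the report bundle."""
    exposures, mediators, outcomes, truth = _load_tables(config)
    exclusion_maps = {
        name: instruments.read_exclusion_list(path)
        for name, path in config.exclusions.items()}

    direct_rows, sens_rows, audits, per_snp_frames = [], [], [], []
    stage1_rows, med_out_rows, mediation_rows = [], [], []
    counts_log = {}

    def _record(res):
        audits.append(res["candidates"])
        counts_log[res["direction"]] = res["counts"]
        if res["failed"]:
            return None
        sens_rows.append(res["sensitivity"])
        per_snp_frames.append(res["per_snp"])
        return res

    # direct exposure → outcome
    for ename, ex in exposures.items():
        for oname, out in outcomes.items():
            res = _record(run_direction(ex, out, config,
                                        exclusion_maps.get(ename)))
            if res:
                direct_rows += _panel_rows(res["direction"], res["panel"],
                                           res["call"])

    # stage 1: exposure → mediator
    stage1_by_exposure: dict[str, mediation.StageOneResult] = {}
    for ename, ex in exposures.items():
        for mname, med in mediators.items():
            res = _record(run_direction(ex, med, config,
                                        exclusion_maps.get(ename)))
            if not res:
                continue
            h = res["harmonized"]
            if len(h) >= 3:
                s1 = mediation.summary_stage_one(h)
                stage1_by_exposure[ename] = s1
                for row, b, s, t, p in (
                        ("intercept", s1.intercept, s1.intercept_se,
                         s1.intercept_t, s1.intercept_p),
                        ("predicted", s1.B1, s1.S1, s1.t, s1.pval)):
                    stage1_rows.append({
                        "exposure": ename, "mediator": mname, "row": row,
                        "B": b, "S": s, "t": t, "P": p, "R2": s1.r2,
                        "method": s1.method})

    # stage 2: mediator → outcome (five-method panel; IVW feeds mediation)
    stage2_by_outcome: dict[str, mediation.StageTwoResult] = {}
    for mname, med in mediators.items():
        for oname, out in outcomes.items():
            res = _record(run_direction(med, out, config,
                                        exclusion_maps.get(mname)))
            if not res:
                continue
            med_out_rows += _panel_rows(res["direction"], res["panel"],
                                        res["call"])
            e = res["panel"].estimates["ivw"]
            stage2_by_outcome[oname] = mediation.StageTwoResult(
                B2=e.B, S2=e.SE, model=e.model or "fixed", n_snps=e.n_snps)

    # product-of-coefficients mediation per triplet
    for ename, s1 in stage1_by_exposure.items():
        for oname, s2 in stage2_by_outcome.items():
            m = mediation.sobel_mediation(s1.B1, s1.S1, s2.B2, s2.S2)
            mediation_rows.append({
                "exposure": ename, "outcome": oname,
                "B1": m.B1, "S1": m.S1, "B2": m.B2, "S2": m.S2,
                "stage2_model": s2.model,
                "Bm": m.Bm, "Sm": m.Sm, "Z": m.Z, "Pm": m.Pm,
                "ci_low": m.ci_low, "ci_high": m.ci_high})

    manifest = {
        "seed": config.seed,
        "config": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                       else v)
                   for k, v in dataclasses.asdict(config).items()
                   if k != "outdir"},  # content-determining settings only
        "stage_counts": counts_log,
        "truth": (None if truth is None else {
            "a": truth.a, "b": truth.b, "c_prime": truth.c_prime,
            "mediated_effect": truth.mediated_effect}),
    }
    report = AnalysisReport(
        direct_effects=pd.DataFrame(direct_rows),
        stage1=pd.DataFrame(stage1_rows),
        mediator_outcome=pd.DataFrame(med_out_rows),
        mediation=pd.DataFrame(mediation_rows),
        sensitivity=pd.DataFrame(sens_rows),
        audit=(pd.concat(audits, ignore_index=True) if audits
               else pd.DataFrame()),
        per_snp=(pd.concat(per_snp_frames, ignore_index=True)
                 if per_snp_frames else pd.DataFrame()),
        manifest=manifest,
    )
    if config.outdir:
        report.write(config.outdir)
    return report
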