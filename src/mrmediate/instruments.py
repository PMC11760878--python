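"""Instrument selection and quality control.

Instrumental variables for two-sample MR must be strongly associated with
the exposure, mutually independent, and free of direct outcome paths.  The
operations here implement the standard QC cascade: genome-wide significance
filtering, greedy LD clumping, F-statistic weak-instrument filtering,
exclusion of variants annotated to confounder phenotypes, and removal of
variants already associated with the outcome.

Every operation works on an audit-friendly candidate table: rows are never
silently discarded — a dropped instrument keeps its row with ``status`` set
to ``"dropped"`` and exactly one ``drop_reason``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .sumstats import HarmonizedTable, SummaryTable

logger = logging.getLogger(__name__)

DROP_REASONS = (
    "subthreshold", "clumped", "weak", "confounder",
    "outcome_associated", "presso_outlier", "missing_in_outcome",
)


@dataclass
class SelectionConfig:
    """Thresholds of the instrument-selection cascade.

    Defaults: genome-wide significance 5e-8; clumping r² 0.001 within a
    10,000 kb window; minimum F-statistic 10; outcome-association exclusion
    at p < 1e-5.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    outcome_p_exclude: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p_threshold", "clump_r2", "clump_window_kb",
                     "f_min", "outcome_p_exclude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_f(beta, se):
    """Single-SNP F-statistic, the square of the Wald z: (beta/se)²."""
    return (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2


def r2_from_f(f, n):
    """Variance explained implied by an F-statistic at sample size n.

    r² = F / (F + n − 2), the exact relation for a univariate regression.
    """
    f = np.asarray(f, dtype=float)
    n = np.asarray(n, dtype=float)
    return f / (f + n - 2.0)


def select_by_pvalue(table: SummaryTable, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Mark genome-wide-significant records as kept candidates.

    Returns the full candidate table (one row per input record) with
    ``f_stat``, ``r2_exposure``, ``status`` and ``drop_reason`` columns;
    records at or above the threshold are dropped with reason
    ``subthreshold``.
    """
    cand = table.df.copy()
    cand["f_stat"] = compute_f(cand["beta"], cand["se"])
    with np.errstate(invalid="ignore"):
        cand["r2_exposure"] = np.where(
            cand["n"].notna(), r2_from_f(cand["f_stat"], cand["n"]), np.nan)
    keep = cand["pval"] < p_threshold
    cand["status"] = np.where(keep, "kept", "dropped")
    cand["drop_reason"] = np.where(keep, "", "subthreshold")
    return cand


def _ld_lookup(ld, a: str, b: str) -> float:
    if ld is None:
        return 1.0  # no panel: same-window pairs treated as in full LD
    key = (a, b) if (a, b) in ld else (b, a)
    if key not in ld:
        logger.warning("clump: LD matrix missing pair (%s, %s); assuming r²=0", a, b)
        return 0.0
    return float(ld[key])


def ld_from_triplets(df: pd.DataFrame) -> dict:
    """Build an LD lookup from a triplet table (variant_id_a, variant_id_b, r2)."""
    return {(a, b): r for a, b, r in
            zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])}


def clump(
    candidates: pd.DataFrame,
    clump_r2: float = 0.001,
    clump_window_kb: float = 10_000.0,
    ld: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Greedy p-value clumping of kept candidates.

    Repeatedly takes the lowest-p remaining candidate (ties broken by
    variant id) and drops every other candidate on the same chromosome
    within ``clump_window_kb`` whose r² with it exceeds ``clump_r2``.
    Without an LD lookup all same-window pairs are treated as correlated
    (distance-only thinning).  Dropped rows get reason ``clumped``.
    """
    cand = candidates.copy()
    kept_mask = cand["status"] == "kept"
    live = cand.loc[kept_mask].sort_values(
        ["pval", "variant_id"], kind="mergesort")
    window = clump_window_kb * 1000.0
    alive = dict.fromkeys(live["variant_id"], True)
    clumped: list[str] = []
    rows = live.set_index("variant_id")
    order = list(rows.index)
    for vid in order:
        if not alive[vid]:
            continue
        lead = rows.loc[vid]
        for other in order:
            if other == vid or not alive[other]:
                continue
            row = rows.loc[other]
            if row["chrom"] != lead["chrom"]:
                continue
            if abs(float(row["pos"]) - float(lead["pos"])) > window:
                continue
            if _ld_lookup(ld, vid, other) > clump_r2:
                alive[other] = False
                clumped.append(other)
    drop = cand["variant_id"].isin(clumped)
    cand.loc[drop, "status"] = "dropped"
    cand.loc[drop, "drop_reason"] = "clumped"
    return cand


def filter_weak(candidates: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Drop kept candidates whose F-statistic does not exceed ``f_min``."""
    cand = candidates.copy()
    weak = (cand["status"] == "kept") & ~(cand["f_stat"] > f_min)
    cand.loc[weak, "status"] = "dropped"
    cand.loc[weak, "drop_reason"] = "weak"
    return cand


def apply_exclusions(candidates: pd.DataFrame,
                     exclusions: Mapping[str, str]) -> pd.DataFrame:
    """Drop candidates listed as confounder-associated.

    ``exclusions`` maps variant id to a phenotype annotation (free text,
    e.g. from an LD-trait lookup); the annotation is retained in the
    ``exclusion_note`` column for the audit log.
    """
    cand = candidates.copy()
    hit = (cand["status"] == "kept") & cand["variant_id"].isin(exclusions)
    cand.loc[hit, "status"] = "dropped"
    cand.loc[hit, "drop_reason"] = "confounder"
    cand["exclusion_note"] = [
        exclusions.get(v, "") if h else ""
        for v, h in zip(cand["variant_id"], hit)]
    return cand


def read_exclusion_list(path) -> dict[str, str]:
    """Read a two-column TSV (variant_id, phenotype) into an exclusion map."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def kept_ids(candidates: pd.DataFrame) -> list[str]:
    return list(candidates.loc[candidates["status"] == "kept", "variant_id"])


def filter_outcome_associated(
    h: HarmonizedTable, outcome_p_exclude: float = 1e-5
) -> tuple[HarmonizedTable, list[str]]:
    """Remove harmonized pairs already associated with the outcome.

    Pairs with outcome p-value below the threshold violate the exclusion
    assumption prima facie and are removed (reason ``outcome_associated``).
    Returns the filtered table and the removed variant ids.
    """
    bad = h.df["pval_y"] < outcome_p_exclude
    removed = list(h.df.loc[bad, "variant_id"])
    return h.subset(~bad), removed
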