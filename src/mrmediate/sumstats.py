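"""Reading, validating, writing and harmonizing GWAS summary statistics.

A summary-statistic table holds one row per biallelic SNP: identifiers,
alleles, effect-allele frequency (EAF), the per-allele effect estimate with
its standard error and p-value, and the per-SNP sample size.  Effects for
binary traits are on the log-odds scale; quantitative traits are in SD or
natural units.

Harmonization aligns an exposure table and an outcome table onto a common
effect allele so that every downstream estimator sees per-SNP effect pairs
(beta_x, beta_y) expressed for the same allele.  Palindromic SNPs (A/T or
C/G) are strand-ambiguous and are resolved — or dropped — by comparing
effect-allele frequencies against 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the TSV dialect
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


@dataclass
class SummaryTable:
    """Validated per-trait summary statistics.

    Attributes
    ----------
    trait_id : str
        Identifier of the trait (e.g. an OpenGWAS-style accession).
    trait_type : str
        ``"quantitative"`` or ``"binary"`` (binary effects are log-odds).
    df : pandas.DataFrame
        One validated record per row, columns :data:`COLUMNS`,
        unique ``variant_id``.
    n_dropped : int
        Rows discarded during validation (invariant violations, indels,
        duplicate ids).
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class HarmonizedTable:
    """Per-SNP exposure/outcome effect pairs on a common effect allele."""

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "HarmonizedTable":
        return HarmonizedTable(self.exposure_id, self.outcome_id,
                               self.df.loc[mask].reset_index(drop=True))


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Enforce record invariants, returning (valid rows, n dropped).

    Alleles are upper-cased; rows are dropped when the variant is not a
    biallelic SNP (indel / multiallelic notation), when alleles coincide,
    when se <= 0 or p-values fall outside (0, 1], or when a stated EAF is
    outside (0, 1).  Duplicate variant ids keep the first occurrence.
    """
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    ok = (
        df["effect_allele"].isin(_BASES)
        & df["other_allele"].isin(_BASES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & df["beta"].notna()
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    ok &= ~df["variant_id"].duplicated()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("validate_records: dropped %d invalid rows", n_dropped)
    return df.loc[ok].reset_index(drop=True), n_dropped


def read_summary_table(
    path,
    trait_id: str,
    trait_type: str = "quantitative",
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> SummaryTable:
    """Read a delimited summary-statistic file into a :class:`SummaryTable`.

    Parameters
    ----------
    column_map : dict, optional
        Maps canonical names (:data:`COLUMNS`) to the source file's header
        names, for exports whose headers differ from the canonical dialect.
    """
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        raise ValueError(f"{path}: empty summary-statistic file")
    column_map = column_map or {}
    rename = {src: canon for canon, src in column_map.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns and c not in ("eaf", "n")]
    # eaf and n may be absent entirely (treated as missing values)
    for opt in ("eaf", "n"):
        if opt not in raw.columns:
            raw[opt] = np.nan
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    raw = raw[COLUMNS]
    df, n_dropped = validate_records(raw)
    return SummaryTable(trait_id=trait_id, trait_type=trait_type,
                        df=df, n_dropped=n_dropped)


def write_summary_table(table: SummaryTable, path) -> None:
    """Write the canonical TSV dialect (round-trips through read)."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def fill_missing_eaf(table: SummaryTable, reference: pd.DataFrame) -> SummaryTable:
    """Complete missing EAF values from a reference frequency panel.

    ``reference`` has columns ``variant_id``, ``effect_allele``, ``eaf``.
    A record matched on its own effect allele takes the reference EAF; a
    record matched on its other allele takes 1 − EAF.  Unmatched records
    keep a missing EAF and are flagged in the ``eaf_unresolved`` column.
    """
    ref = dict(zip(reference["variant_id"],
                   zip(reference["effect_allele"].astype(str).str.upper(),
                       reference["eaf"])))
    df = table.df.copy()
    unresolved = np.zeros(len(df), dtype=bool)
    eaf = df["eaf"].to_numpy(copy=True)
    for i, (vid, ea, oa, cur) in enumerate(
            zip(df["variant_id"], df["effect_allele"], df["other_allele"], eaf)):
        if not np.isnan(cur):
            continue
        hit = ref.get(vid)
        if hit is None:
            unresolved[i] = True
            continue
        ref_allele, ref_eaf = hit
        if ref_allele == ea:
            eaf[i] = ref_eaf
        elif ref_allele == oa:
            eaf[i] = 1.0 - ref_eaf
        else:
            unresolved[i] = True
    df["eaf"] = eaf
    df["eaf_unresolved"] = unresolved
    return SummaryTable(table.trait_id, table.trait_type, df, table.n_dropped)


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_tolerance: float = 0.08,
) -> HarmonizedTable:
    """Align outcome effects onto the exposure's effect allele per SNP.

    For each variant present in both tables:

    * outcome reported for the same allele pair, same orientation → kept;
    * outcome effect allele equals the exposure's other allele → outcome
      beta sign-flipped, EAF complemented, ``flipped=True``;
    * alleles matching only after strand complement → complemented first,
      then oriented as above;
    * palindromic SNPs (A/T, C/G) resolved by ``palindrome_policy``:
      ``"drop"`` removes them; ``"infer_by_eaf"`` keeps them when both EAFs
      lie outside the ambiguous band ``0.5 ± eaf_tolerance``, flipping the
      outcome when the two EAFs sit on opposite sides of 0.5;
    * anything else (strand-incompatible allele sets) is dropped.

    Raises
    ------
    ValueError
        If no variant overlaps between the two tables.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    ex = exposure.df.set_index("variant_id")
    ou = outcome.df.set_index("variant_id")
    common = ex.index.intersection(ou.index)
    if len(common) == 0:
        raise ValueError(
            f"no overlapping variants between {exposure.trait_id} "
            f"and {outcome.trait_id}")

    rows = []
    n_incompatible = 0
    n_palindromic_dropped = 0
    for vid in common:
        e, o = ex.loc[vid], ou.loc[vid]
        ea_x, oa_x = e["effect_allele"], e["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        beta_y, eaf_y = o["beta"], o["eaf"]
        palindromic = _is_palindromic(ea_x, oa_x)

        if {ea_y, oa_y} == {ea_x, oa_x}:
            pass  # same labels, orientation handled below
        elif not palindromic and {_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]} == {ea_x, oa_x}:
            ea_y, oa_y = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
        else:
            n_incompatible += 1
            continue

        flipped = False
        if ea_y == oa_x:  # outcome reported for the opposite allele
            beta_y = -beta_y
            if not np.isnan(eaf_y):
                eaf_y = 1.0 - eaf_y
            flipped = True

        if palindromic:
            if palindrome_policy == "drop":
                n_palindromic_dropped += 1
                continue
            eaf_x = e["eaf"]
            lo, hi = 0.5 - eaf_tolerance, 0.5 + eaf_tolerance
            if (np.isnan(eaf_x) or np.isnan(eaf_y)
                    or lo < eaf_x < hi or lo < eaf_y < hi):
                n_palindromic_dropped += 1
                continue
            if (eaf_x < 0.5) != (eaf_y < 0.5):
                # frequencies disagree: the outcome is on the other strand,
                # which for a palindrome swaps the allele roles
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
                flipped = not flipped

        rows.append({
            "variant_id": vid,
            "chrom": e["chrom"], "pos": e["pos"],
            "effect_allele": ea_x, "other_allele": oa_x,
            "beta_x": e["beta"], "se_x": e["se"], "pval_x": e["pval"],
            "eaf_x": e["eaf"], "n_x": e["n"],
            "beta_y": beta_y, "se_y": o["se"], "pval_y": o["pval"],
            "eaf_y": eaf_y, "n_y": o["n"],
            "palindromic": palindromic, "flipped": flipped,
        })

    if n_incompatible or n_palindromic_dropped:
        logger.info("harmonize: dropped %d strand-incompatible and %d "
                    "palindromic variants", n_incompatible, n_palindromic_dropped)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta_x", "se_x", "pval_x", "eaf_x", "n_x",
                 "beta_y", "se_y", "pval_y", "eaf_y", "n_y",
                 "palindromic", "flipped"])
    return HarmonizedTable(exposure.trait_id, outcome.trait_id, df)
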