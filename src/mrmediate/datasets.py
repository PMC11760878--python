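"""Bundled reference coefficients from a published lipid–telomere–cancer
two-sample MR mediation analysis.

These small tables carry printed stage-1 regression coefficients (lipid
fraction → leukocyte telomere length), IVW odds ratios for telomere length
→ cancer, and the published mediation rows.  They serve as worked-example
inputs: recomputing the product-of-coefficients mediation from the stage-1
coefficients and the TL→lung-cancer odds ratio must reproduce the published
mediated effects.

Lipid fractions: APOA1/APOB (apolipoproteins A-I and B), HDL/LDL
(high-/low-density lipoprotein cholesterol), TG (triglycerides), TC (total
cholesterol), RC (remnant cholesterol).  Cancer outcomes: LUNG (lung),
ESCA (esophageal), HTC (hematological).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "lipid_tl_stage1", "tl_cancer_ivw", "published_mediation",
]


def lipid_tl_stage1() -> pd.DataFrame:
    """Stage-1 (lipid → telomere length) regression coefficient table.

    One intercept row and one slope ("predicted") row per lipid fraction:
    columns lipid, row, B, S, t, pval, r2 (r2 reported on the lipid's
    intercept row in the source layout; repeated here per lipid).
    """
    rows = [
        # lipid, row, B, S, t, pval, r2
        ("APOA1", "intercept", 2.37e-4, 3.08e-4, 0.77, 4.43e-1, 2.55e-4),
        ("APOA1", "predicted", -1.76e-3, 7.82e-3, -0.23, 8.23e-1, 2.55e-4),
        ("APOB", "intercept", -2.59e-4, 4.03e-4, -0.64, 5.22e-1, 1.19e-1),
        ("APOB", "predicted", 2.97e-2, 7.44e-3, 3.99, 1.17e-4, 1.19e-1),
        ("HDL", "intercept", 2.17e-4, 2.97e-4, 0.73, 4.64e-1, 4.61e-4),
        ("HDL", "predicted", 2.35e-3, 7.12e-3, 0.33, 7.42e-1, 4.61e-4),
        ("LDL", "intercept", 2.36e-4, 4.00e-4, 0.59, 5.57e-1, 1.10e-1),
        ("LDL", "predicted", 3.32e-2, 9.53e-3, 3.48, 7.44e-4, 1.10e-1),
        ("TG", "intercept", 1.22e-4, 3.07e-4, 0.39, 6.91e-1, 6.05e-2),
        ("TG", "predicted", 2.17e-2, 6.67e-3, 3.25, 1.40e-3, 6.05e-2),
        ("TC", "intercept", 1.24e-4, 3.60e-4, 0.35, 7.31e-1, 8.76e-2),
        ("TC", "predicted", 3.45e-2, 1.13e-2, 3.05, 2.93e-3, 8.76e-2),
        ("RC", "intercept", 1.86e-4, 7.56e-4, 0.25, 8.09e-1, 6.93e-1),
        ("RC", "predicted", 8.37e-2, 1.31e-2, 6.37, 5.35e-6, 6.93e-1),
    ]
    return pd.DataFrame(rows, columns=["lipid", "row", "B", "S", "t",
                                       "pval", "r2"])


def tl_cancer_ivw() -> pd.DataFrame:
    """Published IVW odds ratios for telomere length → cancer risk."""
    rows = [
        ("LUNG", 1.411, 1e-4),
        ("ESCA", 1.29, 0.039),
        ("HTC", 1.006, 1e-4),
    ]
    return pd.DataFrame(rows, columns=["outcome", "or_ivw", "p_ivw"])


def published_mediation() -> pd.DataFrame:
    """Published mediation rows (lipid → TL → cancer): Bm, Sm, Z, Pm."""
    rows = [
        ("TG", "LUNG", 7.46e-3, 2.62e-3, 2.85, 4.34e-3),
        ("TG", "HTC", 1.21e-4, 4.66e-5, 2.60, 9.28e-3),
        ("TG", "ESCA", 5.51e-3, 3.22e-3, 1.71, 8.66e-2),
        ("TC", "LUNG", 1.19e-2, 4.37e-3, 2.71, 6.64e-3),
        ("TC", "HTC", 1.93e-4, 7.73e-5, 2.50, 1.26e-2),
        ("TC", "ESCA", 8.76e-3, 5.21e-3, 1.68, 9.25e-2),
        ("RC", "LUNG", 2.88e-2, 6.62e-3, 4.35, 1.38e-5),
        ("RC", "HTC", 4.68e-4, 1.30e-4, 3.59, 3.35e-4),
        ("RC", "ESCA", 2.13e-2, 1.11e-2, 1.92, 5.45e-2),
        ("LDL", "LUNG", 1.14e-2, 3.80e-3, 3.00, 2.67e-3),
        ("LDL", "HTC", 1.86e-4, 6.84e-5, 2.72, 6.63e-3),
        ("LDL", "ESCA", 8.43e-3, 4.83e-3, 1.74, 8.10e-2),
        ("APOB", "LUNG", 1.02e-2, 3.09e-3, 3.31, 9.27e-4),
        ("APOB", "HTC", 1.66e-4, 5.65e-5, 2.94, 3.32e-3),
        ("APOB", "ESCA", 7.54e-3, 4.19e-3, 1.80, 7.19e-2),
    ]
    return pd.DataFrame(rows, columns=["lipid", "outcome", "Bm", "Sm",
                                       "Z", "Pm"])
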