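"""Two-step mediation on the exposure → mediator → outcome pathway.

Stage 1 estimates the exposure→mediator effect B₁ (standard error S₁):
either genuine two-stage least squares on an individual-level cohort, or —
when only GWAS summary statistics exist — an intercept-including weighted
regression of mediator-side on exposure-side per-SNP effects that yields
the same report shape (intercept row, slope row, t, p, R²).

Stage 2 estimates the mediator→outcome effect B₂ (S₂) with IVW on the
mediator→outcome harmonized table.

The mediated effect is the product of coefficients with the Sobel
standard error:

    B_m = B₁·B₂,   S_m = sqrt(B₁²S₂² + B₂²S₁²),   Z = B_m/S_m,

with a two-sided normal p-value and 95% CI B_m ± 1.96·S_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .estimators import ivw

__all__ = [
    "StageOneResult", "StageTwoResult", "MediationResult", "CohortData",
    "two_stage_least_squares", "summary_stage_one", "stage_two_ivw",
    "sobel_mediation",
]


@dataclass
class StageOneResult:
    """Exposure→mediator regression in the two-row report shape."""

    intercept: float
    intercept_se: float
    intercept_t: float
    intercept_p: float
    B1: float
    S1: float
    t: float
    pval: float
    r2: float
    method: str = "2sls"  # 2sls | summary_wls


@dataclass
class StageTwoResult:
    B2: float
    S2: float
    model: str = "fixed"  # which IVW model produced it
    n_snps: int = 0


@dataclass
class MediationResult:
    B1: float
    S1: float
    B2: float
    S2: float
    Bm: float
    Sm: float
    Z: float
    Pm: float
    ci_low: float
    ci_high: float


@dataclass
class CohortData:
    """Individual-level data: dosage matrix plus trait vectors."""

    genotypes: np.ndarray  # n_individuals × n_snps, dosages 0/1/2
    snp_ids: list
    exposure: np.ndarray
    mediator: np.ndarray
    outcome: np.ndarray  # binary 0/1

    def __post_init__(self) -> None:
        n = len(self.exposure)
        if self.genotypes.shape[0] != n or len(self.mediator) != n \
                or len(self.outcome) != n:
            raise ValueError("cohort dimensions disagree")


def _drop_collinear(g: np.ndarray, ids: list) -> tuple[np.ndarray, list]:
    """Greedily drop columns that add no rank (constant or collinear)."""
    keep: list[int] = []
    for j in range(g.shape[1]):
        trial = g[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1 and np.ptp(g[:, j]) > 0:
            keep.append(j)
    dropped = [ids[j] for j in range(g.shape[1]) if j not in keep]
    if dropped:
        import logging
        logging.getLogger(__name__).warning(
            "2SLS: dropped %d collinear/constant instruments: %s",
            len(dropped), dropped[:5])
    return g[:, keep], [ids[j] for j in keep]


def two_stage_least_squares(cohort: CohortData,
                            instrument_ids: list | None = None) -> StageOneResult:
    """Two-stage least squares of the mediator on the exposure.

    Stage A regresses the exposure on instrument dosages (with intercept);
    stage B regresses the mediator on the stage-A fitted exposure (with
    intercept).  Reported SEs, t and p (t-distribution, n−2 df) and R² come
    from the stage-B fit — the conventional 2SLS coefficient table shape.
    """
    idx = (list(range(len(cohort.snp_ids))) if instrument_ids is None
           else [cohort.snp_ids.index(v) for v in instrument_ids])
    if not idx:
        raise ValueError("2SLS needs at least one instrument")
    g = np.asarray(cohort.genotypes, dtype=float)[:, idx]
    ids = [cohort.snp_ids[j] for j in idx]
    g, ids = _drop_collinear(g, ids)
    if g.shape[1] == 0:
        raise ValueError("2SLS: all instruments collinear or constant")
    n = g.shape[0]
    if n <= g.shape[1] + 2:
        raise ValueError("2SLS needs n_individuals > n_instruments + 2")
    stage_a = sm.OLS(cohort.exposure, sm.add_constant(g)).fit()
    fitted = stage_a.fittedvalues
    if np.ptp(fitted) == 0:
        raise ValueError("2SLS: singular first stage (constant fitted exposure)")
    xb = sm.add_constant(fitted)
    stage_b = sm.OLS(cohort.mediator, xb).fit()
    b = stage_b.params
    se = stage_b.bse
    tvals = b / se
    dof = n - 2
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return StageOneResult(
        intercept=float(b[0]), intercept_se=float(se[0]),
        intercept_t=float(tvals[0]), intercept_p=float(pvals[0]),
        B1=float(b[1]), S1=float(se[1]), t=float(tvals[1]),
        pval=float(pvals[1]), r2=float(stage_b.rsquared), method="2sls")


def summary_stage_one(table) -> StageOneResult:
    """Summary-level stage 1: weighted regression with intercept.

    Regresses mediator-side per-SNP effects on exposure-side effects with
    weights 1/se_y² (mediator-side variances); reports the intercept row,
    the slope ("Predicted") row with t = B/S and a t-distribution p at k−2
    df, and the weighted R².
    """
    df = table.df if hasattr(table, "df") else table
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    k = len(bx)
    if k < 3:
        raise ValueError("summary_stage_one needs at least 3 instruments")
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    b, se = res.params, res.bse
    tvals = b / se
    dof = k - 2
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return StageOneResult(
        intercept=float(b[0]), intercept_se=float(se[0]),
        intercept_t=float(tvals[0]), intercept_p=float(pvals[0]),
        B1=float(b[1]), S1=float(se[1]), t=float(tvals[1]),
        pval=float(pvals[1]), r2=float(res.rsquared), method="summary_wls")


def stage_two_ivw(table, model: str = "auto") -> StageTwoResult:
    """Stage 2: mediator→outcome effect from IVW on summary data."""
    est = ivw(table, model=model)
    return StageTwoResult(B2=est.B, S2=est.SE, model=est.model or "fixed",
                          n_snps=est.n_snps)


def sobel_mediation(b1: float, s1: float, b2: float, s2: float) -> MediationResult:
    """Product-of-coefficients mediation with the Sobel standard error."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("stage standard errors must be positive")
    bm = b1 * b2
    sm_ = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2))
    z = bm / sm_ if sm_ > 0 else 0.0
    return MediationResult(
        B1=b1, S1=s1, B2=b2, S2=s2, Bm=float(bm), Sm=sm_, Z=float(z),
        Pm=float(2 * stats.norm.sf(abs(z))),
        ci_low=float(bm - 1.96 * sm_), ci_high=float(bm + 1.96 * sm_))
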