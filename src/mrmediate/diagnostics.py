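"""Sensitivity diagnostics for two-sample MR.

Covers heterogeneity (Cochran's Q), directional pleiotropy (MR-Egger
intercept), simulation-based outlier detection (the residual-sum-of-squares
global/outlier test), directionality (Steiger's variance-explained
comparison), and the expected bias and type-I-error inflation from
participant overlap between the exposure and outcome GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import EggerRegression, wald_ratios

__all__ = [
    "HeterogeneityResult", "PleiotropyResult", "PressoResult",
    "SteigerResult", "OverlapBias",
    "cochran_q", "egger_intercept_test", "mr_presso", "steiger",
    "overlap_bias",
]


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pval: float

    @property
    def significant(self) -> bool:
        return self.pval < 0.05


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    per_snp_pvals: list = field(repr=False)
    outlier_ids: list = field(default_factory=list)
    n_sim: int = 0
    seed: int = 0
    # optional distortion report: IVW estimate before/after outlier removal
    distortion: dict | None = None


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pval: float


@dataclass
class OverlapBias:
    overlap_prop: float
    mean_f: float
    assumed_confounded_effect: float
    expected_bias: float
    type1_error: float


def cochran_q(table, b_ivw: float | None = None) -> HeterogeneityResult:
    """Cochran's Q over the per-SNP Wald ratios.

    Q = Σ w_j (r_j − b)² with w_j the inverse ratio variances and b the
    fixed-effect IVW estimate (recomputed when not supplied); p-value from
    chi-square with k−1 degrees of freedom.
    """
    r, se = wald_ratios(table)
    if len(r) < 2:
        raise ValueError("cochran_q needs at least 2 instruments")
    w = 1.0 / se**2
    if b_ivw is None:
        b_ivw = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - b_ivw) ** 2))
    df = len(r) - 1
    return HeterogeneityResult(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(table) -> PleiotropyResult:
    """Directional-pleiotropy test from the MR-Egger intercept."""
    est = EggerRegression().fit(table)
    return PleiotropyResult(intercept=est.intercept_, se=est.intercept_se_,
                            pval=est.intercept_pvalue_)


def _loo_ivw_slopes(bx, by, sy):
    """Leave-one-out fixed-effect IVW slopes b_(−j), vectorized."""
    r = by / bx
    w = (np.abs(bx) / sy) ** 2  # 1/ratio_se² with ratio_se = sy/|bx|
    sw, swr = np.sum(w), np.sum(w * r)
    return (swr - w * r) / (sw - w)


def mr_presso(table, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0) -> PressoResult:
    """Simulation-based global heterogeneity and outlier test.

    The observed global statistic is the residual sum of squares
    Σ_j (β̂_Yj − b_(−j)·β̂_Xj)² with leave-one-out IVW slopes b_(−j).  The
    null distribution simulates β̂*_Yj ~ N(b_(−j)·β̂_Xj, se_Yj) ``n_sim``
    times; Monte-Carlo p-values use (exceedances+1)/(n_sim+1).  Per-SNP
    terms are tested the same way with a Bonferroni threshold
    ``outlier_alpha``/k to flag outliers.
    """
    df = table.df if hasattr(table, "df") else table
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    k = len(bx)
    if k < 4:
        raise ValueError("mr_presso needs at least 4 instruments")
    b_loo = _loo_ivw_slopes(bx, by, sy)
    expected = b_loo * bx
    obs_terms = (by - expected) ** 2
    obs_rss = float(np.sum(obs_terms))

    rng = np.random.default_rng(seed)
    sim_y = rng.normal(expected, sy, size=(n_sim, k))
    sim_terms = (sim_y - expected) ** 2
    sim_rss = sim_terms.sum(axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
    per_snp = (np.sum(sim_terms >= obs_terms, axis=0) + 1) / (n_sim + 1)
    thresh = outlier_alpha / k
    ids = df["variant_id"].to_numpy() if "variant_id" in df else np.arange(k)
    outliers = [ids[j] for j in range(k) if per_snp[j] < thresh]
    return PressoResult(global_rss=obs_rss, global_pval=global_p,
                        per_snp_pvals=list(map(float, per_snp)),
                        outlier_ids=outliers, n_sim=n_sim, seed=seed)


def presso_distortion(table, result: PressoResult) -> dict:
    """Optional distortion report: fixed-effect IVW before and after
    removing flagged outliers, and the relative change."""
    from .estimators import ivw

    before = ivw(table, model="fixed").B
    df = table.df if hasattr(table, "df") else table
    keep = ~df["variant_id"].isin(result.outlier_ids)
    after = before
    if keep.sum() >= 2 and keep.sum() < len(df):
        after = ivw(df.loc[keep], model="fixed").B
    change = (before - after) / after if after != 0 else np.nan
    return {"b_before": float(before), "b_after": float(after),
            "relative_change": float(change)}


def steiger(table, n_exposure: int | None = None,
            n_outcome: int | None = None) -> SteigerResult:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-SNP r² is recovered from the F-statistic as r² = F/(F+n−2) and
    summed across instruments on each side; the p-value is a two-sample
    z-test on the Fisher-transformed multiple correlations r = sqrt(Σr²).
    For binary outcomes the same relation is applied on the log-odds scale
    (an approximation).
    """
    df = table.df if hasattr(table, "df") else table
    if n_exposure is None:
        n_exposure = _table_n(df, "n_x", "exposure")
    if n_outcome is None:
        n_outcome = _table_n(df, "n_y", "outcome")
    fx = (df["beta_x"].to_numpy(float) / df["se_x"].to_numpy(float)) ** 2
    fy = (df["beta_y"].to_numpy(float) / df["se_y"].to_numpy(float)) ** 2
    r2x = float(np.sum(fx / (fx + n_exposure - 2)))
    r2y = float(np.sum(fy / (fy + n_outcome - 2)))
    r2x, r2y = min(r2x, 1.0 - 1e-12), min(r2y, 1.0 - 1e-12)
    zx, zy = np.arctanh(np.sqrt(r2x)), np.arctanh(np.sqrt(r2y))
    denom = np.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    z = (zx - zy) / denom
    return SteigerResult(r2_exposure=r2x, r2_outcome=r2y,
                         correct_direction=bool(r2x > r2y),
                         pval=float(2 * stats.norm.sf(abs(z))))


def _table_n(df, col: str, side: str) -> float:
    if col not in df or df[col].isna().all():
        raise ValueError(f"steiger: sample size missing for the {side} side")
    return float(np.nanmedian(df[col].to_numpy(float)))


def overlap_bias(mean_f: float, overlap_prop: float,
                 assumed_confounded_effect: float, alpha: float = 0.05,
                 se_unit: float = 1.0) -> OverlapBias:
    """Expected bias and type-I error under exposure/outcome sample overlap.

    The bias estimation factor follows the two-sample overlap literature:
    expected bias = overlap × confounded effect / F̄, where F̄ is the mean
    instrument F-statistic and the confounded effect is the (assumed)
    observational association absorbed by the overlap.  The type-I error
    is P(|Z + bias/se_unit| > z_{1−α/2}) under the normal approximation,
    with ``se_unit`` the null standard-error scale of the causal estimate.
    """
    if mean_f <= 0:
        raise ValueError("mean_f must be positive")
    if not 0 <= overlap_prop <= 1:
        raise ValueError("overlap_prop must lie in [0, 1]")
    bias = overlap_prop * assumed_confounded_effect / mean_f
    lam = bias / se_unit
    zc = stats.norm.ppf(1 - alpha / 2)
    t1 = float(stats.norm.sf(zc - lam) + stats.norm.cdf(-zc - lam))
    return OverlapBias(overlap_prop=overlap_prop, mean_f=mean_f,
                       assumed_confounded_effect=assumed_confounded_effect,
                       expected_bias=float(bias), type1_error=t1)
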