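"""Synthetic cohorts and three-trait GWAS summary statistics.

The generator realizes the causal structure the mediation analysis
assumes — SNPs → exposure → mediator → (binary) outcome — with knobs for
each way the instrumental-variable assumptions can fail: direct SNP→outcome
effects (horizontal pleiotropy, balanced or directional), a shared latent
confounder of exposure and outcome, and participant overlap between the
exposure and outcome GWAS samples.

Structure of a simulated cohort:

* biallelic SNPs with MAF uniform on ``maf_range``, simulated independent
  (no LD) — the post-clumping state every summary-data estimator assumes;
* a fraction of SNPs are exposure instruments (effects γ_j on X) and the
  remainder are mediator instruments (direct effects α_j on M), mirroring
  real designs where exposure and mediator draw on distinct GWAS hits;
* X and M are quantitative with unit variance in expectation;
* the outcome is a liability threshold with standard-logistic noise, so
  per-SNP logistic regression recovers log-odds effects on the natural
  scale (``outcome_prevalence=None`` keeps the continuous liability).

Per-SNP scans are closed-form simple linear regression for quantitative
traits and a vectorized Newton (IRLS) logistic regression for the binary
outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mediation import CohortData
from .sumstats import COLUMNS, SummaryTable, validate_records

__all__ = [
    "SimulationConfig", "TruthRecord",
    "simulate_cohort", "gwas_scan", "make_three_gwas", "subsample_ids",
    "simulate_summary_pairs",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated three-trait GWAS design.

    Defaults emulate a well-powered quantitative-trait GWAS feeding a
    two-sample MR: 50 independent SNPs, 20,000 individuals per trait GWAS,
    per-allele instrument effects of SD 0.1 on unit-variance traits
    (mean single-SNP F ≈ 70 at this n), exposure→mediator effect a = 0.3,
    mediator→outcome log-odds b = 0.4, no direct effect, no pleiotropy,
    no confounding, no sample overlap, 10% outcome prevalence.
    """

    seed: int
    n_snps: int = 50
    n_individuals: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.10           # SNP→exposure effect scale
    alpha_sd: float = 0.10           # direct SNP→mediator effect scale
    mediator_instrument_frac: float = 0.5
    effect_x_to_m: float = 0.3       # a
    effect_m_to_y: float = 0.4       # b, log-odds per unit mediator
    direct_x_to_y: float = 0.0       # c', log-odds per unit exposure
    pleiotropy_frac: float = 0.0     # fraction of SNPs with direct Y effects
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0     # nonzero → directional pleiotropy
    confounding_effect: float = 0.0  # shared latent on exposure and liability
    overlap_prop: float = 0.0        # shared exposure/outcome GWAS individuals
    outcome_prevalence: float | None = 0.1  # None → continuous liability

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi == 0.5)):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("mediator_instrument_frac", "pleiotropy_frac", "overlap_prop"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthRecord:
    """Simulator ground truth for recovery tests."""

    gamma: np.ndarray  # SNP→exposure
    alpha: np.ndarray  # direct SNP→mediator
    delta: np.ndarray  # direct SNP→outcome (pleiotropy)
    a: float
    b: float
    c_prime: float
    mediated_effect: float = field(init=False)

    def __post_init__(self) -> None:
        self.mediated_effect = self.a * self.b


def _pool_size(config: SimulationConfig) -> int:
    n = config.n_individuals
    return 3 * n - int(round(config.overlap_prop * n))


def simulate_cohort(config: SimulationConfig,
                    n_total: int | None = None) -> tuple[CohortData, TruthRecord]:
    """Draw one cohort (dosages + traits) and its ground truth.

    Noise variances are scaled so X and M have unit variance in
    expectation; an infeasible variance budget (genetic + confounder
    variance ≥ 1) raises.
    """
    rng = np.random.default_rng(config.seed)
    n_total = _pool_size(config) if n_total is None else n_total
    k = config.n_snps
    maf = rng.uniform(*config.maf_range, size=k)

    n_med = int(round(config.mediator_instrument_frac * k))
    is_med = np.zeros(k, dtype=bool)
    is_med[k - n_med:] = True
    gamma = np.where(~is_med, rng.normal(0.0, config.gamma_sd, size=k), 0.0)
    alpha = np.where(is_med, rng.normal(0.0, config.alpha_sd, size=k), 0.0)
    delta = np.zeros(k)
    n_pleio = int(round(config.pleiotropy_frac * k))
    if n_pleio and (config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0):
        which = rng.choice(k, size=n_pleio, replace=False)
        draw = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                          size=n_pleio)
        # directional pleiotropy is defined on the exposure-increasing
        # allele orientation (the orientation Egger regression uses)
        orient = np.where(gamma[which] < 0, -1.0, 1.0)
        delta[which] = orient * draw

    dosage_var = 2.0 * maf * (1.0 - maf)
    gvar_x = float(np.sum(dosage_var * gamma**2))
    conf2 = config.confounding_effect**2
    if gvar_x + conf2 > 1.0:
        raise ValueError(
            f"infeasible exposure variance budget: genetic {gvar_x:.3f} "
            f"+ confounder {conf2:.3f} > 1")
    a = config.effect_x_to_m
    gvar_m = float(np.sum(dosage_var * alpha**2))
    if a**2 + gvar_m > 1.0:
        raise ValueError(
            f"infeasible mediator variance budget: a² {a**2:.3f} "
            f"+ genetic {gvar_m:.3f} > 1")

    g = rng.binomial(2, maf, size=(n_total, k)).astype(np.int8)
    gf = g.astype(float)
    u = rng.normal(size=n_total)
    sd_x = np.sqrt(max(1.0 - gvar_x - conf2, 0.0))
    sd_m = np.sqrt(max(1.0 - a**2 - gvar_m, 0.0))
    x = (gf @ gamma + config.confounding_effect * u
         + rng.normal(0.0, 1.0, size=n_total) * sd_x)
    m = (a * x + gf @ alpha
         + rng.normal(0.0, 1.0, size=n_total) * sd_m)
    signal = (config.direct_x_to_y * x + config.effect_m_to_y * m
              + gf @ delta + config.confounding_effect * u)
    if config.outcome_prevalence is None:
        # quantitative outcome: unit-variance normal noise
        y = signal + rng.normal(size=n_total)
    else:
        # liability threshold with standard-logistic noise, so per-SNP
        # logistic regression recovers log-odds effects on their own scale
        liability = signal + rng.logistic(0.0, 1.0, size=n_total)
        thr = np.quantile(liability, 1.0 - config.outcome_prevalence)
        y = (liability > thr).astype(float)

    snp_ids = [f"rs{j + 1}" for j in range(k)]
    cohort = CohortData(genotypes=g, snp_ids=snp_ids,
                        exposure=x, mediator=m, outcome=y)
    truth = TruthRecord(gamma=gamma, alpha=alpha, delta=delta,
                        a=a, b=config.effect_m_to_y,
                        c_prime=config.direct_x_to_y)
    return cohort, truth


# ---------------------------------------------------------------------------
# per-SNP association scans

def _linear_scan(g: np.ndarray, y: np.ndarray):
    """Closed-form simple linear regression of y on each dosage column."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        resid_var = (syy - beta * sxy) / (n - 2)
        se = np.sqrt(resid_var / sxx)
    beta[sxx == 0] = np.nan
    return beta, se


def _logistic_scan(g: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-10):
    """Vectorized Newton logistic regression y ~ intercept + dosage,
    one fit per column of g."""
    n, k = g.shape
    ybar = y.mean()
    a = np.full(k, np.log(ybar / (1 - ybar)))
    b = np.zeros(k)
    i00 = i01 = i11 = det = np.ones(k)
    for _ in range(max_iter):
        eta = np.clip(a + g * b, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        s0 = r.sum(axis=0)
        s1 = (r * g).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * g).sum(axis=0)
        i11 = (w * g * g).sum(axis=0)
        det = i00 * i11 - i01**2
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (i11 * s0 - i01 * s1) / det
            db = (i00 * s1 - i01 * s0) / det
        bad = ~np.isfinite(da) | ~np.isfinite(db)
        da[bad] = 0.0
        db[bad] = 0.0
        a += da
        b += db
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(i00 / det)
    mono = g.std(axis=0) == 0
    b = b.copy()
    b[mono] = np.nan
    return b, se


def _snp_positions(k: int):
    """Independent-SNP layout: round-robin over 22 chromosomes with 25 Mb
    spacing, so distance-only clumping never links two SNPs."""
    chrom = [str((j % 22) + 1) for j in range(k)]
    pos = [1_000_000 + (j // 22) * 25_000_000 for j in range(k)]
    return chrom, pos


def gwas_scan(cohort: CohortData, trait: str,
              subsample_ids: np.ndarray | None = None) -> SummaryTable:
    """Per-SNP association scan of one trait in a subsample.

    Quantitative traits use closed-form simple linear regression; a binary
    outcome uses per-SNP logistic regression (log-odds betas).  Wald
    p-values from the normal distribution.  Monomorphic SNPs yield missing
    betas and are dropped by record validation.
    """
    from scipy import stats

    if trait not in ("exposure", "mediator", "outcome"):
        raise ValueError(f"unknown trait {trait!r}")
    y = np.asarray(getattr(cohort, trait), dtype=float)
    g = np.asarray(cohort.genotypes, dtype=float)
    if subsample_ids is not None:
        subsample_ids = np.asarray(subsample_ids)
        if subsample_ids.max(initial=-1) >= g.shape[0]:
            raise ValueError("subsample ids exceed cohort size")
        g = g[subsample_ids]
        y = y[subsample_ids]
    n = g.shape[0]
    binary = trait == "outcome" and set(np.unique(y)) <= {0.0, 1.0}
    beta, se = (_logistic_scan(g, y) if binary else _linear_scan(g, y))
    with np.errstate(invalid="ignore", divide="ignore"):
        pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    chrom, pos = _snp_positions(len(cohort.snp_ids))
    df = pd.DataFrame({
        "variant_id": cohort.snp_ids,
        "chrom": chrom, "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "eaf": g.mean(axis=0) / 2.0,
        "beta": beta, "se": se, "pval": pval, "n": n,
    })[COLUMNS]
    valid, n_dropped = validate_records(df)
    return SummaryTable(
        trait_id=trait,
        trait_type="binary" if binary else "quantitative",
        df=valid, n_dropped=n_dropped)


def subsample_ids(config: SimulationConfig):
    """Index layout of the three GWAS subsamples within the cohort pool.

    Exposure and outcome share the first/last ``overlap_prop`` fraction of
    their individuals; the mediator sample is disjoint from both.  Returns
    (exposure_ids, mediator_ids, outcome_ids).
    """
    n = config.n_individuals
    ov = int(round(config.overlap_prop * n))
    ids_x = np.arange(0, n)
    ids_y = np.arange(n - ov, 2 * n - ov)
    ids_m = np.arange(2 * n - ov, 3 * n - ov)
    return ids_x, ids_m, ids_y


def make_three_gwas(config: SimulationConfig, cohort: CohortData | None = None,
                    truth: TruthRecord | None = None):
    """Simulate the exposure / mediator / outcome GWAS triplet.

    The exposure and outcome scans share ``overlap_prop`` of their
    individuals; the mediator scan is disjoint from both.  Returns
    (exposure, mediator, outcome, truth).
    """
    if cohort is None:
        cohort, truth = simulate_cohort(config)
    ids_x, ids_m, ids_y = subsample_ids(config)
    need = int(ids_m[-1]) + 1
    if cohort.genotypes.shape[0] < need:
        raise ValueError(
            f"overlap_prop={config.overlap_prop} needs {need} individuals, "
            f"cohort has {cohort.genotypes.shape[0]}")
    exposure = gwas_scan(cohort, "exposure", ids_x)
    mediator = gwas_scan(cohort, "mediator", ids_m)
    outcome = gwas_scan(cohort, "outcome", ids_y)
    return exposure, mediator, outcome, truth


def simulate_summary_pairs(seed: int, n_snps: int = 50, true_effect: float = 0.0,
                           gamma_sd: float = 0.15, se_x: float = 0.02,
                           se_y: float = 0.04, pleiotropy_mean: float = 0.0,
                           pleiotropy_sd: float = 0.0) -> pd.DataFrame:
    """Directly simulate harmonized per-SNP effect pairs.

    The exact sampling model of summary-data MR: β̂_Xj ~ N(γ_j, se_x²),
    β̂_Yj ~ N(effect·γ_j + δ_j, se_y²) with independent errors (no sample
    overlap).  Orders of magnitude faster than a cohort simulation; used
    for estimator calibration experiments.
    """
    rng = np.random.default_rng(seed)
    gamma = rng.normal(0.0, gamma_sd, size=n_snps)
    if pleiotropy_sd > 0 or pleiotropy_mean != 0:
        # directional pleiotropy acts on the exposure-increasing orientation
        delta = np.where(gamma < 0, -1.0, 1.0) * rng.normal(
            pleiotropy_mean, pleiotropy_sd, size=n_snps)
    else:
        delta = np.zeros(n_snps)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(true_effect * gamma + delta, se_y)
    return pd.DataFrame({
        "variant_id": [f"rs{j + 1}" for j in range(n_snps)],
        "beta_x": beta_x, "se_x": se_x,
        "pval_x": 2.0 * _norm_sf(np.abs(beta_x / se_x)),
        "beta_y": beta_y, "se_y": se_y,
        "pval_y": 2.0 * _norm_sf(np.abs(beta_y / se_y)),
    })


def _norm_sf(z):
    from scipy import stats
    return stats.norm.sf(z)
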