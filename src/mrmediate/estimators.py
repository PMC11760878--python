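"""The five two-sample MR estimators and the causal-call rules.

Each estimator consumes per-SNP harmonized effect pairs (β̂_Xj, β̂_Yj with
standard errors) and returns a causal effect B on the outcome scale per
unit exposure, its standard error, a two-sided normal p-value, and the
odds-ratio transform exp(B) with 95% CI exp(B ± 1.96·SE).

The shared primitive is the per-SNP Wald ratio r_j = β̂_Yj / β̂_Xj with
first-order standard error se_j = se_Yj / |β̂_Xj|:

* **IVW** — inverse-variance weighted mean of the ratios; fixed-effect
  SE (Σw)^{-1/2}, optionally inflated by max(1, sqrt(Q/(k−1))) under the
  multiplicative random-effects model.  ``model="auto"`` switches to
  random effects when Cochran's Q is significant at 0.05.
* **MR-Egger** — weighted regression of β̂_Y on β̂_X with an intercept;
  the slope is the causal estimate and a nonzero intercept indicates
  directional horizontal pleiotropy.
* **Weighted median** — the ratio at cumulative standardized weight 0.5;
  consistent when ≥50% of the weight comes from valid instruments.
* **Simple / weighted mode** — the maximizer of a normal-kernel density
  over the ratios; consistent when the largest homogeneous cluster of
  instruments is valid.

Estimators are scikit-learn style: construct with hyperparameters, call
``fit(table)`` with a :class:`~mrmediate.sumstats.HarmonizedTable` (or a
DataFrame bearing ``beta_x, se_x, beta_y, se_y``), then read fitted
attributes (``estimate_``, ``se_``, ``pvalue_``, ``odds_ratio_``, ...).
Module-level functions wrap them for one-line use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# results containers

@dataclass
class MREstimate:
    """One estimator's result on one analysis direction."""

    method: str
    B: float
    SE: float
    pval: float
    OR: float
    ci_low: float
    ci_high: float
    n_snps: int
    model: str | None = None  # fixed | random, IVW only


@dataclass
class MethodPanel:
    """The five-method bundle for one exposure→outcome direction."""

    estimates: dict[str, MREstimate]
    directionally_consistent: bool
    p_ivw: float


@dataclass
class CausalCall:
    """Decision on a panel: significance requires p_IVW < alpha AND all
    five effect estimates sharing a sign; direction from the IVW OR."""

    significant: bool
    direction: str  # risk | protective | null


METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


def _as_frame(table) -> pd.DataFrame:
    df = table.df if hasattr(table, "df") else table
    need = {"beta_x", "se_x", "beta_y", "se_y"}
    if not need.issubset(df.columns):
        raise ValueError(f"harmonized table must have columns {sorted(need)}")
    return df


def wald_ratios(table) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP causal ratios and first-order standard errors.

    Pairs with β̂_X = 0 are excluded with a logged warning (the ratio is
    undefined there).
    """
    df = _as_frame(table)
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    nz = bx != 0
    if not nz.all():
        logger.warning("wald_ratios: excluded %d pairs with beta_x = 0",
                       int((~nz).sum()))
    return by[nz] / bx[nz], sy[nz] / np.abs(bx[nz])


def _normal_p(z) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _to_estimate(method, b, se, n_snps, model=None, pval=None) -> MREstimate:
    if pval is None:
        pval = _normal_p(b / se) if se > 0 else 1.0
    return MREstimate(
        method=method, B=float(b), SE=float(se), pval=float(pval),
        OR=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.96 * se)),
        ci_high=float(np.exp(b + 1.96 * se)),
        n_snps=int(n_snps), model=model,
    )


class _MRBase(BaseEstimator):
    """Shared fit plumbing: Wald ratios, OR/CI transform, result export."""

    _min_snps = 2

    def fit(self, table):
        df = _as_frame(table)
        r, se = wald_ratios(df)
        if len(r) < self._min_snps:
            raise ValueError(
                f"{type(self).__name__} needs at least {self._min_snps} "
                f"instruments, got {len(r)}")
        self.n_snps_ = len(r)
        self._fit(df, r, se)
        self.odds_ratio_ = float(np.exp(self.estimate_))
        self.ci_low_ = float(np.exp(self.estimate_ - 1.96 * self.se_))
        self.ci_high_ = float(np.exp(self.estimate_ + 1.96 * self.se_))
        return self

    def result_(self, method_name: str, model: str | None = None) -> MREstimate:
        return _to_estimate(method_name, self.estimate_, self.se_,
                            self.n_snps_, model=model, pval=self.pvalue_)


class IVW(_MRBase):
    """Inverse-variance weighted estimator.

    Parameters
    ----------
    model : {"fixed", "random", "auto"}
        Fixed-effect SE, multiplicative random-effects SE, or automatic
        selection (random effects when Cochran's Q p < 0.05).

    Fitted attributes include ``q_``, ``q_pvalue_`` (heterogeneity) and
    ``model_used_``.
    """

    def __init__(self, model: str = "auto"):
        self.model = model

    def _fit(self, df, r, se):
        if self.model not in ("fixed", "random", "auto"):
            raise ValueError(f"unknown IVW model {self.model!r}")
        w = 1.0 / se**2
        b = float(np.sum(w * r) / np.sum(w))
        se_fixed = float(np.sum(w) ** -0.5)
        k = len(r)
        q = float(np.sum(w * (r - b) ** 2))
        q_p = float(stats.chi2.sf(q, k - 1))
        inflate = max(1.0, np.sqrt(q / (k - 1)))
        if self.model == "fixed":
            used = "fixed"
        elif self.model == "random":
            used = "random"
        else:
            used = "random" if q_p < 0.05 else "fixed"
        self.estimate_ = b
        self.se_ = se_fixed * inflate if used == "random" else se_fixed
        self.pvalue_ = _normal_p(b / self.se_)
        self.q_, self.q_df_, self.q_pvalue_ = q, k - 1, q_p
        self.model_used_ = used


class EggerRegression(_MRBase):
    """MR-Egger: weighted regression of outcome on exposure effects with an
    intercept, after orienting every pair to β̂_X ≥ 0.

    Slope = causal estimate; intercept = average directional pleiotropy.
    Standard errors carry the multiplicative inflation
    max(1, sqrt(RSS_w/(k−2))).
    """

    _min_snps = 3

    def __init__(self):
        pass

    def _fit(self, df, r, se):
        bx = df["beta_x"].to_numpy(float)
        by = df["beta_y"].to_numpy(float)
        sy = df["se_y"].to_numpy(float)
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        sigma = float(np.sqrt(res.scale))
        adj = 1.0 / min(1.0, sigma)  # floor the residual scale at 1
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(res.bse[0] * adj)
        self.intercept_pvalue_ = _normal_p(self.intercept_ / self.intercept_se_)
        self.estimate_ = float(res.params[1])
        self.se_ = float(res.bse[1] * adj)
        self.pvalue_ = _normal_p(self.estimate_ / self.se_)
        self.residual_scale_ = sigma


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)  # midpoint convention
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


class WeightedMedian(_MRBase):
    """Weighted-median estimator with parametric-bootstrap SE.

    The estimate is the Wald ratio at cumulative standardized
    inverse-variance weight 0.5 (linear interpolation between order
    statistics at their weight midpoints).  The SE resamples
    (β̂_X, β̂_Y) from their sampling distributions ``n_boot`` times.
    """

    _min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, df, r, se):
        w = 1.0 / se**2
        self.estimate_ = _weighted_median(r, w)
        self.se_ = _bootstrap_se(df, self._point, self.n_boot, self.seed)
        self.pvalue_ = _normal_p(self.estimate_ / self.se_)

    @staticmethod
    def _point(bx, by, sx, sy):
        nz = bx != 0
        r = by[nz] / bx[nz]
        se = sy[nz] / np.abs(bx[nz])
        return _weighted_median(r, 1.0 / se**2)


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    if np.ptp(r) == 0:
        return float(r[0])
    s = min(np.std(r, ddof=1), stats.iqr(r) / 1.349)
    h = phi * 0.9 * s * len(r) ** (-1 / 5)
    if h == 0:
        return float(np.average(r, weights=w))
    grid = np.linspace(r.min(), r.max(), 1000)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - r[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


class ModeEstimator(_MRBase):
    """Mode-based estimator (simple or inverse-variance weighted).

    The point estimate maximizes a normal-kernel density over the Wald
    ratios with bandwidth phi × 0.9 × min(sd, iqr/1.349) × k^(−1/5) on a
    1000-point grid spanning the ratios; SE by seeded parametric
    bootstrap.  Identical ratios (zero bandwidth) return the common value.
    """

    _min_snps = 3

    def __init__(self, weighted: bool = True, phi: float = 1.0,
                 n_boot: int = 1000, seed: int = 0):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, df, r, se):
        w = 1.0 / se**2 if self.weighted else np.ones_like(r)
        self.estimate_ = _mode_point(r, w, self.phi)
        self.se_ = _bootstrap_se(df, self._point, self.n_boot, self.seed)
        self.pvalue_ = _normal_p(self.estimate_ / self.se_)

    def _point(self, bx, by, sx, sy):
        nz = bx != 0
        r = by[nz] / bx[nz]
        se = sy[nz] / np.abs(bx[nz])
        w = 1.0 / se**2 if self.weighted else np.ones_like(r)
        return _mode_point(r, w, self.phi)


def _bootstrap_se(df, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample effect pairs from N(obs, se)."""
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sx = df["se_x"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        boots[i] = point_fn(bxs, bys, sx, sy)
    return float(np.std(boots, ddof=1))


# ---------------------------------------------------------------------------
# functional wrappers

def ivw(table, model: str = "auto") -> MREstimate:
    est = IVW(model=model).fit(table)
    return est.result_("ivw", model=est.model_used_)


def egger(table) -> tuple[MREstimate, dict]:
    est = EggerRegression().fit(table)
    intercept = {"intercept": est.intercept_, "se": est.intercept_se_,
                 "pval": est.intercept_pvalue_}
    return est.result_("egger"), intercept


def weighted_median(table, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(table).result_(
        "weighted_median")


def mode_estimate(table, weighted: bool = True, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    name = "weighted_mode" if weighted else "simple_mode"
    return ModeEstimator(weighted=weighted, phi=phi, n_boot=n_boot,
                         seed=seed).fit(table).result_(name)


def method_panel(table, model: str = "auto", phi: float = 1.0,
                 n_boot: int = 1000, seed: int = 0) -> MethodPanel:
    """Run all five estimators on one harmonized table."""
    estimates = {
        "ivw": ivw(table, model=model),
        "egger": egger(table)[0],
        "weighted_median": weighted_median(table, n_boot=n_boot, seed=seed),
        "simple_mode": mode_estimate(table, weighted=False, phi=phi,
                                     n_boot=n_boot, seed=seed + 1),
        "weighted_mode": mode_estimate(table, weighted=True, phi=phi,
                                       n_boot=n_boot, seed=seed + 2),
    }
    bs = np.array([e.B for e in estimates.values()])
    consistent = bool(np.all(bs > 0) or np.all(bs < 0))
    return MethodPanel(estimates=estimates,
                       directionally_consistent=consistent,
                       p_ivw=estimates["ivw"].pval)


def causal_call(panel: MethodPanel, alpha: float = 0.05) -> CausalCall:
    """Apply the three causal-call rules (no multiple-testing correction):

    1. all five effect estimates share a sign;
    2. the IVW p-value is below ``alpha``;
    3. risk vs protective from whether the IVW OR exceeds 1.
    """
    significant = bool(panel.p_ivw < alpha and panel.directionally_consistent)
    if not significant:
        direction = "null"
    else:
        or_ivw = panel.estimates["ivw"].OR
        direction = "risk" if or_ivw > 1 else ("protective" if or_ivw < 1 else "null")
    if direction == "null":
        significant = False
    return CausalCall(significant=significant, direction=direction)
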