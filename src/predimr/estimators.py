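"""Causal-effect estimators for summary-level two-sample MR.

All estimators consume a :class:`~predimr.instruments.HarmonizedInstrumentSet`
with per-SNP exposure effects gamma_j (SE sigma_xj) and outcome effects
Gamma_j (SE sigma_yj) on the same allele, and return estimates on the log
scale (the outcome GWAS scale — log-odds for binary outcomes) alongside
the exponentiated odds-ratio reporting scale.

Conventions shared by every method:

* p-values and confidence intervals use normal quantiles (not t), so the
  plain, robust and bootstrap variants are directly comparable;
* standard errors carry a multiplicative random-effects scaling
  ``max(1, sqrt(RSS_w / (n - p)))`` — over-dispersion inflates them,
  under-dispersion never shrinks them;
* the robust variants fit the same weighted regression by iteratively
  reweighted M-estimation with the Tukey bisquare loss (tuning constant
  4.685) and report robust (sandwich) standard errors; non-convergence
  falls back to the plain fit with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .instruments import HarmonizedInstrumentSet

__all__ = [
    "MrEstimate",
    "EggerResult",
    "LooResult",
    "EstimationError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "leave_one_out",
]

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)  # 1.959964...

TUKEY_C = 4.685
ROBUST_MAXITER = 200
ROBUST_TOL = 1e-8


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate from one method, log scale + OR scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            object.__setattr__(self, "ci_low", self.beta - Z95 * self.se)
        if np.isnan(self.ci_high):
            object.__setattr__(self, "ci_high", self.beta + Z95 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        lo, hi = self.or_ci
        return dict(
            method=self.method,
            beta=self.beta,
            se=self.se,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            pvalue=self.pvalue,
            odds_ratio=self.odds_ratio,
            or_ci_low=lo,
            or_ci_high=hi,
            n_snps=self.n_snps,
        )


@dataclass(frozen=True)
class EggerResult:
    """Egger regression: causal slope plus the pleiotropy intercept test."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float

    @property
    def intercept_or(self) -> float:
        """exp(intercept) — the scale on which the intercept is reported."""
        return float(np.exp(self.intercept))

    def to_dict(self) -> dict:
        d = self.slope.to_dict()
        d.update(
            intercept=self.intercept,
            intercept_se=self.intercept_se,
            intercept_pvalue=self.intercept_pvalue,
            intercept_or=self.intercept_or,
        )
        return d


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out estimates: one per omitted SNP plus the full fit."""

    full: MrEstimate
    omitted: list[tuple[str, MrEstimate]]

    def __len__(self) -> int:
        return len(self.omitted) + 1

    def rows(self) -> list[dict]:
        out = [dict(omitted="(none)", **self.full.to_dict())]
        for rsid, est in self.omitted:
            out.append(dict(omitted=rsid, **est.to_dict()))
        return out


def wald_ratio(gamma: float, se_x: float, Gamma: float, se_y: float) -> tuple[float, float]:
    """Single-SNP ratio estimate Gamma/gamma with first-order delta SE."""
    if gamma == 0:
        raise EstimationError("Wald ratio undefined for gamma = 0")
    return Gamma / gamma, se_y / abs(gamma)


def _two_sided_p(beta: float, se: float) -> float:
    if se <= 0:  # degenerate exact fit
        return 1.0 if beta == 0 else 0.0
    return float(2 * stats.norm.sf(abs(beta) / se))


def _scale_factor(resid_w: np.ndarray, n_params: int) -> float:
    """Multiplicative random-effects SE inflation, floored at 1."""
    n = resid_w.size
    if n <= n_params:
        return 1.0
    return max(1.0, float(np.sqrt(np.sum(resid_w**2) / (n - n_params))))


def _robust_fit(X: np.ndarray, y: np.ndarray) -> sm.robust.robust_linear_model.RLMResults | None:
    """Tukey-bisquare IRLS fit; None on non-convergence."""
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=TUKEY_C))
            res = model.fit(maxiter=ROBUST_MAXITER, tol=ROBUST_TOL)
    except Exception:  # singular design, etc.
        return None
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        return None
    return res


def ivw(
    data: HarmonizedInstrumentSet,
    robust: bool = False,
    scale_se: bool = True,
) -> MrEstimate:
    """Inverse-variance-weighted estimate.

    Weighted zero-intercept regression of Gamma on gamma with weights
    1/sigma_y^2; the plain estimator has the closed form
    ``sum(gamma*Gamma/s^2) / sum(gamma^2/s^2)``. With a single SNP (and
    SE scaling off) it reduces exactly to the Wald ratio.
    """
    g, sx, G, sy = data.arrays()
    n = g.size
    min_n = 3 if robust else (2 if scale_se else 1)
    if n < min_n:
        raise EstimationError(
            f"IVW (robust={robust}, scale_se={scale_se}) needs >= {min_n} SNPs, got {n}"
        )

    gw, Gw = g / sy, G / sy  # precision-scaled: unweighted OLS == WLS
    sxx = float(np.sum(gw * gw))
    beta = float(np.sum(gw * Gw)) / sxx
    se = float(np.sqrt(1.0 / sxx))
    method = "ivw"

    if robust:
        res = _robust_fit(gw[:, None], Gw)
        if res is None:
            logger.warning("robust IVW did not converge; falling back to plain fit")
        else:
            beta = float(res.params[0])
            se = float(res.bse[0])
            method = "ivw_robust"
    if scale_se:
        se *= _scale_factor(Gw - beta * gw, 1)
    return MrEstimate(method, beta, se, _two_sided_p(beta, se), n)


def mr_egger(
    data: HarmonizedInstrumentSet,
    robust: bool = False,
    scale_se: bool = True,
) -> EggerResult:
    """Egger regression: Gamma = theta0 + beta * gamma, weights 1/sigma_y^2.

    Requires exposure effects oriented positive (harmonize guarantees it;
    enforced here regardless). The intercept theta0 estimates the average
    directional pleiotropic effect; its test is the pleiotropy diagnostic.
    """
    g, sx, G, sy = data.arrays()
    n = g.size
    if n < 3:
        raise EstimationError(f"MR-Egger needs >= 3 SNPs, got {n}")
    flip = np.sign(g)
    flip[flip == 0] = 1.0
    g, G = g * flip, G * flip
    if np.ptp(g) == 0:
        raise EstimationError("MR-Egger: all exposure effects equal (collinear design)")

    w = 1.0 / sy
    X = np.column_stack([w, g * w])  # intercept and slope in precision-scaled space
    Y = G * w
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ Y)
    cov = np.linalg.inv(XtX)
    theta0, beta = float(coef[0]), float(coef[1])
    se0, se1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    method = "egger"

    if robust:
        res = _robust_fit(X, Y)
        if res is None:
            logger.warning("robust Egger did not converge; falling back to plain fit")
        else:
            theta0, beta = float(res.params[0]), float(res.params[1])
            se0, se1 = float(res.bse[0]), float(res.bse[1])
            method = "egger_robust"
    if scale_se:
        f = _scale_factor(Y - theta0 * w - beta * g * w, 2)
        se0, se1 = se0 * f, se1 * f

    slope = MrEstimate(method, beta, se1, _two_sided_p(beta, se1), n)
    return EggerResult(slope, theta0, se0, _two_sided_p(theta0, se0))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of per-SNP ratios.

    Sort ratios ascending; at cumulative-weight midpoints
    p_j = cumsum(w)_j - w_j/2 interpolate (p, ratio) at p = 0.5, clamping
    to the extreme ratios when 0.5 falls outside [p_1, p_n].
    """
    order = np.argsort(ratios, kind="mergesort")
    b = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, b))


def weighted_median(
    data: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-SNP ratios Gamma_j/gamma_j are weighted by gamma_j^2/sigma_yj^2
    (inverse variance of the ratio, leading order); the estimate is the
    weighted median; its SE is the SD of the estimate over ``n_boot``
    replicates resampling gamma_j* ~ N(gamma_j, sigma_xj^2) and
    Gamma_j* ~ N(Gamma_j, sigma_yj^2). Consistent when at least half the
    total weight comes from valid instruments.
    """
    g, sx, G, sy = data.arrays()
    n = g.size
    if n < 3:
        raise EstimationError(f"weighted median needs >= 3 SNPs, got {n}")
    if np.any(g == 0):
        raise EstimationError("weighted median undefined when any gamma = 0")
    w = g**2 / sy**2
    est = _weighted_median(G / g, w)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gs = rng.normal(g, sx, size=(n_boot, n))
    Gs = rng.normal(G, sy, size=(n_boot, n))
    gs[gs == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(Gs[i] / gs[i], gs[i] ** 2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return MrEstimate("weighted_median", est, se, _two_sided_p(est, se), n)


def cochran_q(data: HarmonizedInstrumentSet, beta: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of per-SNP effects about a causal slope.

    Q = sum((Gamma_j - beta*gamma_j)^2 / sigma_yj^2), df = n - 1.
    """
    g, _, G, sy = data.arrays()
    if g.size < 2:
        raise EstimationError("Cochran's Q needs >= 2 SNPs")
    q = float(np.sum((G - beta * g) ** 2 / sy**2))
    df = g.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(
    data: HarmonizedInstrumentSet,
    method: str = "ivw_robust",
    **kwargs,
) -> LooResult:
    """Re-estimate with each SNP omitted in turn.

    ``method`` is one of ``ivw``, ``ivw_robust``, ``egger``,
    ``egger_robust``, ``weighted_median``. An influential or pleiotropic
    variant shows up as the omission that moves the estimate most.
    """
    if data.n_snps < 4:
        raise EstimationError("leave-one-out needs >= 4 SNPs")

    def run(d: HarmonizedInstrumentSet) -> MrEstimate:
        if method in ("ivw", "ivw_robust"):
            return ivw(d, robust=method.endswith("robust"), **kwargs)
        if method in ("egger", "egger_robust"):
            return mr_egger(d, robust=method.endswith("robust"), **kwargs).slope
        if method == "weighted_median":
            return weighted_median(d, **kwargs)
        raise EstimationError(f"unknown leave-one-out method '{method}'")

    full = run(data)
    omitted = []
    for rsid in data.rsids:
        try:
            omitted.append((rsid, run(data.drop([rsid]))))
        except EstimationError as exc:
            raise EstimationError(f"leave-one-out failed omitting {rsid}: {exc}") from exc
    return LooResult(full, omitted)
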