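"""Simulation-based horizontal-pleiotropy detection (MR-PRESSO style).

Three nested tests on a harmonized instrument set:

* **global test** — observed residual sum of squares, with each SNP's
  residual taken about the leave-one-out IVW slope, compared against a
  parametric-simulation null;
* **outlier test** — per-SNP squared residual against its own simulated
  null, Bonferroni-adjusted;
* **distortion test** — whether removing the flagged outliers moves the
  IVW estimate more than removing the same number of random SNPs would.

Plain (non-robust) IVW is used throughout, matching the procedure's
definition; robust IVW is reserved for headline estimates. All empirical
p-values use add-one smoothing, (1 + #{sim >= obs}) / (n_sim + 1), so
they always lie in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import EstimationError, MrEstimate, ivw
from .instruments import HarmonizedInstrumentSet

__all__ = [
    "MrpressoResult",
    "mrpresso_global",
    "mrpresso_outliers",
    "mrpresso_distortion",
    "run_mrpresso",
]


@dataclass
class MrpressoResult:
    rss_obs: float
    p_global: float
    outlier_pvalues: dict[str, float]  # Bonferroni-adjusted, per SNP
    outliers: list[str]
    raw_estimate: MrEstimate
    corrected_estimate: MrEstimate | None
    distortion_percent: float | None
    distortion_pvalue: float | None
    n_sim: int
    seed: int

    def to_dict(self) -> dict:
        return dict(
            rss_obs=self.rss_obs,
            p_global=self.p_global,
            outlier_pvalues=self.outlier_pvalues,
            outliers=self.outliers,
            raw_estimate=self.raw_estimate.to_dict(),
            corrected_estimate=(
                None if self.corrected_estimate is None else self.corrected_estimate.to_dict()
            ),
            distortion_percent=self.distortion_percent,
            distortion_pvalue=self.distortion_pvalue,
            n_sim=self.n_sim,
            seed=self.seed,
        )


def _loo_slopes(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out plain IVW slopes, closed form.

    With S_xy = sum(g*G/s^2) and S_xx = sum(g^2/s^2), omitting SNP j gives
    (S_xy - g_j G_j/s_j^2) / (S_xx - g_j^2/s_j^2). Vectorised; used both
    on observed data and inside the simulation loop.
    """
    t = g * G / sy**2
    u = g**2 / sy**2
    num = t.sum(axis=-1, keepdims=True) - t
    den = u.sum(axis=-1, keepdims=True) - u
    return num / den


def _rss_and_resid(
    g: np.ndarray, G: np.ndarray, sy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP weighted squared residuals about LOO slopes, and their sum."""
    beta_loo = _loo_slopes(g, G, sy)
    r2 = (G - beta_loo * g) ** 2 / sy**2
    return r2, r2.sum(axis=-1)


def _simulate_null(
    g: np.ndarray,
    sx: np.ndarray,
    sy: np.ndarray,
    beta_loo_obs: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated per-SNP squared residuals (n_sim, n) and total RSS (n_sim,).

    Under the no-pleiotropy null each SNP's outcome effect is centred on
    its own leave-one-out prediction beta_loo_j * gamma_j.
    """
    n = g.size
    g_sim = rng.normal(g, sx, size=(n_sim, n))
    G_sim = rng.normal(beta_loo_obs * g, sy, size=(n_sim, n))
    return _rss_and_resid(g_sim, G_sim, sy)


def mrpresso_global(
    data: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Global pleiotropy test: observed RSS vs its simulated null."""
    g, sx, G, sy = _check(data)
    rng = _rng(seed)
    _, rss_obs = _rss_and_resid(g, G, sy)
    beta_loo = _loo_slopes(g, G, sy)
    _, rss_sim = _simulate_null(g, sx, sy, beta_loo, n_sim, rng)
    p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    return float(rss_obs), float(p)


def mrpresso_outliers(
    data: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[dict[str, float], list[str]]:
    """Per-SNP outlier test: Bonferroni-adjusted empirical p-values."""
    g, sx, G, sy = _check(data)
    rng = _rng(seed)
    r2_obs, _ = _rss_and_resid(g, G, sy)
    beta_loo = _loo_slopes(g, G, sy)
    r2_sim, _ = _simulate_null(g, sx, sy, beta_loo, n_sim, rng)
    raw = (1 + np.sum(r2_sim >= r2_obs, axis=0)) / (n_sim + 1)
    adj = np.minimum(raw * g.size, 1.0)
    pvals = dict(zip(data.rsids, adj.astype(float)))
    outliers = [r for r, p in pvals.items() if p < alpha]
    return pvals, outliers


def mrpresso_distortion(
    data: HarmonizedInstrumentSet,
    outliers: list[str],
    n_sim_distortion: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, MrEstimate]:
    """Distortion test comparing raw and outlier-corrected IVW estimates.

    The corrected estimate is plain IVW on the non-outlier SNPs. The
    observed distortion, 100*(b_corr - b_raw)/|b_corr|, is compared
    against the distortions obtained by removing ``len(outliers)`` SNPs
    chosen uniformly at random (two-sided empirical p).
    """
    if not outliers:
        raise EstimationError("distortion test needs at least one outlier")
    keep = data.drop(outliers)
    if keep.n_snps < 3:
        raise EstimationError("distortion test needs >= 3 non-outlier SNPs")
    rng = _rng(seed)
    g, sx, G, sy = data.arrays()

    raw = ivw(data, robust=False, scale_se=True)
    corrected = ivw(keep, robust=False, scale_se=True)
    d_obs = 100.0 * (corrected.beta - raw.beta) / abs(corrected.beta)

    n, k = g.size, len(outliers)
    u = g**2 / sy**2
    t = g * G / sy**2
    b_raw = t.sum() / u.sum()
    d_null = np.empty(n_sim_distortion)
    for i in range(n_sim_distortion):
        drop = rng.choice(n, size=k, replace=False)
        b_sub = (t.sum() - t[drop].sum()) / (u.sum() - u[drop].sum())
        d_null[i] = 100.0 * (b_sub - b_raw) / abs(b_sub)
    p = (1 + int(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_sim_distortion + 1)
    return float(d_obs), float(p), corrected


def run_mrpresso(
    data: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MrpressoResult:
    """Full MR-PRESSO pass: global, outlier, then distortion when outliers exist."""
    rng = np.random.default_rng(seed)
    rss_obs, p_global = mrpresso_global(data, n_sim, rng)
    pvals, outliers = mrpresso_outliers(data, n_sim, rng, alpha)
    raw = ivw(data, robust=False, scale_se=True)

    corrected = None
    d_obs = d_p = None
    if outliers and data.n_snps - len(outliers) >= 3:
        d_obs, d_p, corrected = mrpresso_distortion(data, outliers, n_sim, rng)
    return MrpressoResult(
        rss_obs=rss_obs,
        p_global=p_global,
        outlier_pvalues=pvals,
        outliers=outliers,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_percent=d_obs,
        distortion_pvalue=d_p,
        n_sim=n_sim,
        seed=seed,
    )


def _check(data: HarmonizedInstrumentSet):
    if data.n_snps < 4:
        raise EstimationError(f"MR-PRESSO needs >= 4 SNPs, got {data.n_snps}")
    return data.arrays()


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
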