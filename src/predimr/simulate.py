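"""Seeded generators for every input the two analysis arms consume.

The MR generator emulates the summary-statistic world the estimators
assume: per-SNP exposure effects drawn around true values with GWAS-scale
standard errors ``1/sqrt(2*maf*(1-maf)*n)`` (a standardized-trait
approximation, reused on the log-odds scale for binary outcomes), outcome
effects centred on ``beta_true * gamma_j`` plus an optional pleiotropic
offset, planted outliers, a disease GWAS for the exclusion filter, a
block-diagonal LD matrix, and deliberate strand / allele-order corruption
of the outcome records for the harmonizer to undo. Ground truth for every
random choice travels with the data.

The meta-analysis generator emulates a corpus of observational studies
with a true pooled log-risk, between-study heterogeneity, and an optional
small-study bias for the publication-bias tests to detect.

One seed per dataset; independent sub-streams per component, so changing
one component's size does not shift another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta import StudyRecord, Z95
from .sumstats import LdMatrix, SummaryStatSet

__all__ = [
    "MrSimConfig",
    "MetaSimConfig",
    "SyntheticTruth",
    "gen_mr_dataset",
    "gen_meta_studies",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MrSimConfig:
    """Conditions for one synthetic two-sample MR dataset.

    Defaults mirror the fasting-glucose → CAD setting the package
    targets: 28 approximately independent instruments from an exposure
    GWAS of 133,010 individuals, per-allele effects of 0.05–0.15 trait
    SD, and a causal odds ratio of 1.26 per exposure unit.
    """

    n_snps: int = 28
    n_exposure: int = 133_010
    n_outcome: int = 300_000
    beta_true: float = float(np.log(1.26))
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_range: tuple[float, float] = (0.05, 0.15)
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0  # fraction of instruments carrying the pleiotropy
    outlier_indices: tuple[int, ...] = ()
    outlier_offset: float = 0.0  # in units of sigma_y
    frac_strand_flip: float = 0.0
    frac_allele_swap: float = 0.0
    frac_palindromic: float = 0.0
    n_null_snps: int = 0  # extra no-effect SNPs (for the significance filter)
    disease_assoc_indices: tuple[int, ...] = ()  # instruments planted as disease-associated
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimConfigError("n_snps must be >= 1")
        for name in ("maf_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise SimConfigError(f"{name} must be ordered")
        for name in ("frac_strand_flip", "frac_allele_swap", "frac_palindromic"):
            f = getattr(self, name)
            if not 0 <= f <= 1:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise SimConfigError(f"unknown pleiotropy_mode '{self.pleiotropy_mode}'")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise SimConfigError("pleiotropy_frac must be in [0, 1]")
        if any(i < 0 or i >= self.n_snps for i in self.outlier_indices):
            raise SimConfigError("outlier_indices out of range")
        if any(i < 0 or i >= self.n_snps for i in self.disease_assoc_indices):
            raise SimConfigError("disease_assoc_indices out of range")
        if not 0 <= self.ld_within_r2 <= 1:
            raise SimConfigError("ld_within_r2 must be in [0, 1]")


@dataclass(frozen=True)
class MetaSimConfig:
    """Conditions for one synthetic observational-study corpus.

    Defaults mirror the coronary-artery-disease corpus the package
    targets: 21 cohorts, true pooled relative risk 1.16, modest
    between-study spread.
    """

    k_studies: int = 21
    mu_true: float = float(np.log(1.16))
    tau: float = 0.05
    se_range: tuple[float, float] = (0.05, 0.3)
    label_scheme: dict | None = None  # label_key -> sequence of values, round-robin
    small_study_bias: float = 0.0
    effect_measure: str = "RR"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise SimConfigError("k_studies must be >= 1")
        if self.tau < 0:
            raise SimConfigError("tau must be >= 0")
        lo, hi = self.se_range
        if not 0 < lo <= hi:
            raise SimConfigError("se_range must be positive and ordered")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset, aligned row-for-row."""

    config: dict
    per_snp: pd.DataFrame | None = None
    per_study: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {"config": self.config}
        if self.per_snp is not None:
            out["per_snp"] = self.per_snp.to_dict("records")
        if self.per_study is not None:
            out["per_study"] = self.per_study.to_dict("records")
        return out


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _pvalue_from_z(z: np.ndarray) -> np.ndarray:
    return np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)


def gen_mr_dataset(
    config: MrSimConfig,
) -> tuple[SummaryStatSet, SummaryStatSet, SummaryStatSet, LdMatrix, SyntheticTruth]:
    """Generate (exposure, outcome, disease, LD, truth) for one MR run.

    The first ``n_snps`` variants are true instruments; ``n_null_snps``
    additional variants carry no exposure effect. The outcome set is the
    one subjected to strand/allele corruption; the truth table records,
    per SNP, the pre-corruption effect pair both as drawn and re-oriented
    to a positive exposure effect (the form harmonization returns).
    """
    cfg = config
    (
        rng_geno,
        rng_expo,
        rng_out,
        rng_plei,
        rng_dis,
        rng_corr,
    ) = _streams(cfg.seed, 6)

    n_inst, n_null = cfg.n_snps, cfg.n_null_snps
    n_total = n_inst + n_null
    rsids = [f"rs{i + 1:06d}" for i in range(n_total)]

    # --- genome geometry: LD blocks laid 2 Mb apart, 5 blocks per chromosome
    block_size = max(1, cfg.ld_block_size)
    block_of = np.arange(n_total) // block_size
    chrom = (block_of // 5 + 1).astype(int)
    pos = np.empty(n_total, dtype=int)
    for i in range(n_total):
        within = i % block_size
        pos[i] = 1_000_000 + (block_of[i] % 5) * 2_000_000 + within * 10_000

    # --- allele frequencies & alleles
    maf = rng_geno.uniform(*cfg.maf_range, size=n_total)
    n_palin = int(round(cfg.frac_palindromic * n_total))
    palin_idx = rng_geno.choice(n_total, size=n_palin, replace=False) if n_palin else np.array([], int)
    is_palin = np.zeros(n_total, bool)
    is_palin[palin_idx] = True
    # palindromic variants need an unambiguous frequency for inference
    maf[is_palin] = rng_geno.uniform(cfg.maf_range[0], min(0.35, cfg.maf_range[1]), size=n_palin)
    # effect allele may be either the minor or the major allele
    eaf = np.where(rng_geno.random(n_total) < 0.5, maf, 1 - maf)
    pair_choice = rng_geno.integers(0, len(_NONPALINDROMIC_PAIRS), size=n_total)
    ea = np.array([_NONPALINDROMIC_PAIRS[c][0] for c in pair_choice], dtype=object)
    oa = np.array([_NONPALINDROMIC_PAIRS[c][1] for c in pair_choice], dtype=object)
    palin_choice = rng_geno.integers(0, len(_PALINDROMIC_PAIRS), size=n_total)
    ea[is_palin] = [_PALINDROMIC_PAIRS[c][0] for c in palin_choice[is_palin]]
    oa[is_palin] = [_PALINDROMIC_PAIRS[c][1] for c in palin_choice[is_palin]]

    # --- true and observed exposure effects
    gamma_true = np.zeros(n_total)
    mag = rng_geno.uniform(*cfg.gamma_range, size=n_inst)
    sign = np.where(rng_geno.random(n_inst) < 0.5, 1.0, -1.0)
    gamma_true[:n_inst] = mag * sign
    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_outcome)
    gamma_obs = rng_expo.normal(gamma_true, se_x)

    # --- pleiotropy (optionally confined to a random subset of instruments)
    alpha = np.zeros(n_total)
    sd = cfg.pleiotropy_sd
    n_invalid = int(round(cfg.pleiotropy_frac * n_inst))
    invalid = rng_plei.choice(n_inst, size=n_invalid, replace=False)
    if cfg.pleiotropy_mode == "balanced" and sd > 0:
        alpha[invalid] = rng_plei.normal(0.0, sd, size=n_invalid)
    elif cfg.pleiotropy_mode == "directional" and sd > 0:
        alpha[invalid] = rng_plei.normal(sd, sd / 2, size=n_invalid)
    elif cfg.pleiotropy_mode == "inside_violating" and sd > 0:
        mean_g = np.mean(np.abs(gamma_true[:n_inst]))
        alpha[invalid] = 0.5 * sd * gamma_true[invalid] / mean_g + rng_plei.normal(
            0.0, sd / 2, size=n_invalid
        )

    # --- observed outcome effects (+ planted outliers)
    # pleiotropy is anchored to the exposure-increasing allele (a "directional"
    # direct effect means directional after orientation, which is where the
    # estimators live); recoding the record must not flip its sign
    orient_true = np.where(gamma_true < 0, -1.0, 1.0)
    alpha = orient_true * alpha
    Gamma_obs = rng_out.normal(cfg.beta_true * gamma_true + alpha, se_y)
    is_outlier = np.zeros(n_total, bool)
    for j in cfg.outlier_indices:
        Gamma_obs[j] += cfg.outlier_offset * se_y[j]
        is_outlier[j] = True

    # --- disease GWAS: p-values planted on either side of the 0.05 filter
    disease_assoc = np.zeros(n_total, bool)
    disease_assoc[list(cfg.disease_assoc_indices)] = True
    p_dis = rng_dis.uniform(np.nextafter(0.05, 1), 1.0, size=n_total)
    p_dis[disease_assoc] = rng_dis.uniform(1e-4, 0.05, size=int(disease_assoc.sum()))
    se_d = se_x.copy()
    z_d = stats.norm.isf(p_dis / 2) * np.where(rng_dis.random(n_total) < 0.5, 1, -1)
    beta_d = z_d * se_d

    # --- corruption of the outcome records
    out_ea, out_oa = ea.copy(), oa.copy()
    out_Gamma, out_eaf = Gamma_obs.copy(), eaf.copy()
    corruption = np.array(["none"] * n_total, dtype=object)
    nonpal = np.where(~is_palin)[0]
    rng_corr.shuffle(nonpal)
    n_flip = int(round(cfg.frac_strand_flip * n_total))
    n_swap = int(round(cfg.frac_allele_swap * n_total))
    flip_idx = nonpal[:n_flip]
    swap_idx = nonpal[n_flip : n_flip + n_swap]
    for j in flip_idx:  # other strand, same coding: content unchanged
        out_ea[j] = _COMPLEMENT[out_ea[j]]
        out_oa[j] = _COMPLEMENT[out_oa[j]]
        corruption[j] = "strand_flip"
    for j in swap_idx:  # genuine allele recoding
        out_ea[j], out_oa[j] = out_oa[j], out_ea[j]
        out_Gamma[j] = -out_Gamma[j]
        out_eaf[j] = 1 - out_eaf[j]
        corruption[j] = "allele_swap"
    # palindromic variants: recode a random half, frequency inference undoes it
    for j in palin_idx:
        if rng_corr.random() < 0.5:
            out_ea[j], out_oa[j] = out_oa[j], out_ea[j]
            out_Gamma[j] = -out_Gamma[j]
            out_eaf[j] = 1 - out_eaf[j]
            corruption[j] = "palindromic_swap"

    def _frame(beta, se, p, ea_, oa_, eaf_, n_):
        return pd.DataFrame(
            dict(
                rsid=rsids,
                chrom=chrom.astype(str),
                pos=pos,
                effect_allele=list(ea_),
                other_allele=list(oa_),
                eaf=eaf_,
                beta=beta,
                se=se,
                pvalue=p,
                n=float(n_),
            )
        )

    exposure = SummaryStatSet(
        "exposure",
        _frame(gamma_obs, se_x, _pvalue_from_z(gamma_obs / se_x), ea, oa, eaf, cfg.n_exposure),
        "quantitative",
        "mmol/L",
    )
    outcome = SummaryStatSet(
        "outcome",
        _frame(out_Gamma, se_y, _pvalue_from_z(out_Gamma / se_y), out_ea, out_oa, out_eaf, cfg.n_outcome),
        "binary",
        "log-odds",
    )
    disease = SummaryStatSet(
        "disease",
        _frame(beta_d, se_d, p_dis, ea, oa, eaf, cfg.n_exposure),
        "binary",
        "log-odds",
    )

    # --- block-diagonal LD
    r2 = np.eye(n_total)
    if block_size > 1 and cfg.ld_within_r2 > 0:
        for b in np.unique(block_of):
            members = np.where(block_of == b)[0]
            for i in members:
                for j in members:
                    if i != j:
                        r2[i, j] = cfg.ld_within_r2
    ld = LdMatrix(list(rsids), r2, pos={r: int(p) for r, p in zip(rsids, pos)})

    orient = np.where(gamma_obs < 0, -1.0, 1.0)
    truth = SyntheticTruth(
        config=asdict(cfg),
        per_snp=pd.DataFrame(
            dict(
                rsid=rsids,
                is_instrument=np.arange(n_total) < n_inst,
                gamma_true=gamma_true,
                alpha=alpha,
                gamma_obs=gamma_obs,
                Gamma_obs=Gamma_obs,
                gamma_oriented=np.abs(gamma_obs),
                Gamma_oriented=orient * Gamma_obs,
                se_x=se_x,
                se_y=se_y,
                eaf=eaf,
                is_outlier=is_outlier,
                is_palindromic=is_palin,
                disease_associated=disease_assoc,
                corruption=corruption,
            )
        ),
    )
    return exposure, outcome, disease, ld, truth


def gen_meta_studies(
    config: MetaSimConfig,
) -> tuple[list[StudyRecord], SyntheticTruth]:
    """Generate a corpus of study records with known pooled effect.

    theta_i ~ N(mu_true, tau^2); se_i ~ U(se_range);
    y_i ~ N(theta_i + small_study_bias * se_i, se_i^2); reported on the
    ratio scale with 95% CI exp(y +/- 1.959964*se).
    """
    cfg = config
    rng_theta, rng_se, rng_y = _streams(cfg.seed, 3)
    k = cfg.k_studies
    theta = rng_theta.normal(cfg.mu_true, cfg.tau, size=k)
    se = rng_se.uniform(*cfg.se_range, size=k)
    y = rng_y.normal(theta + cfg.small_study_bias * se, se)

    scheme = cfg.label_scheme or {}
    records = []
    for i in range(k):
        labels = {key: vals[i % len(vals)] for key, vals in scheme.items()} or None
        records.append(
            StudyRecord(
                study_id=f"study_{i + 1:02d}",
                effect_measure=cfg.effect_measure,
                estimate=float(np.exp(y[i])),
                ci_low=float(np.exp(y[i] - Z95 * se[i])),
                ci_high=float(np.exp(y[i] + Z95 * se[i])),
                outcome="synthetic",
                labels=labels,
            )
        )
    truth = SyntheticTruth(
        config=asdict(cfg),
        per_study=pd.DataFrame(
            dict(
                study_id=[r.study_id for r in records],
                theta=theta,
                se=se,
                y=y,
            )
        ),
    )
    return records, truth
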