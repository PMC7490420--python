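"""Simulation benchmarks of statistical calibration and correctness.

Each function runs a self-contained simulation study against the
synthetic-data generator's ground truth — oracle equivalence for the
closed-form estimators, parameter recovery and interval coverage for
IVW, intercept-test calibration for Egger regression, contamination
robustness for the weighted median, detection operating characteristics
for MR-PRESSO, and recovery for the meta-analysis arm — and returns the
measured quantities. All replicate seeds derive deterministically from
one master seed.

Problem sizes default to the desk-scale study conditions the package
targets (28 fasting-glucose-like instruments from an exposure GWAS of
133,010; a 21-study observational corpus with true pooled RR 1.16); the
methods note discusses the choices.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .estimators import ivw, mr_egger, weighted_median
from .instruments import harmonize, ld_clump
from .meta import egger_bias_test, pool_studies
from .mrpresso import mrpresso_global, mrpresso_outliers
from .simulate import MetaSimConfig, MrSimConfig, gen_meta_studies, gen_mr_dataset

__all__ = [
    "oracle_equivalence",
    "ivw_parameter_recovery",
    "egger_intercept_type1",
    "median_vs_ivw_contamination",
    "mrpresso_outlier_detection",
    "mrpresso_null_uniformity",
    "harmonization_recovery",
    "clump_brute_force_check",
    "meta_parameter_recovery",
    "meta_egger_bias_power",
]

#: causal effect used throughout the MR recovery suites (OR 1.26 per unit)
BETA_TRUE = float(np.log(1.26))
#: pooled log-RR used in the meta-analysis recovery suite
MU_TRUE = float(np.log(1.16))


def _sub_seeds(master_seed: int, n: int) -> np.ndarray:
    """n deterministic sub-seeds (< 2**31) from one master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31, size=n)


def _random_fixture(rng: np.random.Generator, n: int = 10):
    from .instruments import HarmonizedInstrumentSet
    import pandas as pd

    gamma = rng.uniform(0.05, 0.2, n)
    se_x = rng.uniform(0.002, 0.01, n)
    se_y = rng.uniform(0.005, 0.05, n)
    Gamma = rng.normal(0.3 * gamma, se_y)
    df = pd.DataFrame(
        dict(
            rsid=[f"rs{i}" for i in range(n)],
            effect_allele="A",
            other_allele="G",
            gamma=gamma,
            se_x=se_x,
            Gamma=Gamma,
            se_y=se_y,
            eaf_x=0.3,
            eaf_y=0.3,
        )
    )
    return HarmonizedInstrumentSet("exp", "out", df)


def oracle_equivalence(n_fixtures: int = 100, seed: int = 0) -> dict:
    """Worst-case relative error of IVW and Egger against closed forms.

    The oracles are the inverse-variance sums for the zero-intercept
    slope and the explicit 2x2 normal equations for the intercept model,
    computed independently of the estimator code paths.
    """
    rng = np.random.default_rng(seed)
    worst_ivw = worst_egger = 0.0
    for _ in range(n_fixtures):
        d = _random_fixture(rng, n=int(rng.integers(5, 20)))
        g, _, G, sy = d.arrays()
        w = 1.0 / sy**2
        beta_o = np.sum(w * g * G) / np.sum(w * g**2)
        se_o = np.sqrt(1.0 / np.sum(w * g**2))
        est = ivw(d, scale_se=False)
        worst_ivw = max(
            worst_ivw,
            abs(est.beta - beta_o) / abs(beta_o),
            abs(est.se - se_o) / se_o,
        )

        sw, swx = w.sum(), (w * g).sum()
        swxx, swy, swxy = (w * g * g).sum(), (w * G).sum(), (w * g * G).sum()
        det = sw * swxx - swx**2
        theta0_o = (swxx * swy - swx * swxy) / det
        beta1_o = (sw * swxy - swx * swy) / det
        res = mr_egger(d, scale_se=False)
        worst_egger = max(
            worst_egger,
            abs(res.intercept - theta0_o) / max(abs(theta0_o), 1e-12),
            abs(res.slope.beta - beta1_o) / abs(beta1_o),
        )
    return {"ivw_max_rel_err": worst_ivw, "egger_max_rel_err": worst_egger,
            "n_fixtures": n_fixtures}


def ivw_parameter_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Bias and 95%-CI coverage of plain IVW on clean 28-SNP datasets."""
    seeds = _sub_seeds(seed, n_reps)
    ests, covered = [], 0
    for s in seeds:
        e, o, *_ = gen_mr_dataset(MrSimConfig(n_snps=28, beta_true=BETA_TRUE, seed=int(s)))
        est = ivw(harmonize(e, o))
        ests.append(est.beta)
        covered += est.ci_low <= BETA_TRUE <= est.ci_high
    ests = np.asarray(ests)
    mc_se = float(np.std(ests, ddof=1) / np.sqrt(n_reps))
    return {
        "mean_estimate": float(np.mean(ests)),
        "beta_true": BETA_TRUE,
        "abs_bias": float(abs(np.mean(ests) - BETA_TRUE)),
        "mc_se": mc_se,
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def egger_intercept_type1(n_reps: int = 1000, seed: int = 0,
                          pleiotropy_sd: float = 0.002) -> dict:
    """Egger intercept rejection rate at alpha=0.05 under balanced
    pleiotropy (InSIDE holds; the null of no *directional* pleiotropy is
    true). ``pleiotropy_sd`` is scaled to produce the moderate
    between-SNP heterogeneity the package's target setting exhibits.
    """
    seeds = _sub_seeds(seed, n_reps)
    rej = 0
    for s in seeds:
        e, o, *_ = gen_mr_dataset(
            MrSimConfig(n_snps=28, beta_true=BETA_TRUE, pleiotropy_mode="balanced",
                        pleiotropy_sd=pleiotropy_sd, seed=int(s))
        )
        rej += mr_egger(harmonize(e, o)).intercept_pvalue < 0.05
    return {"type1_rate": rej / n_reps, "alpha": 0.05, "n_reps": n_reps}


def median_vs_ivw_contamination(n_reps: int = 500, seed: int = 0) -> dict:
    """Paired bias of weighted median vs IVW with 30% directional-invalid
    instruments (the median's headline robustness property)."""
    seeds = _sub_seeds(seed, n_reps)
    med, ivw_b = [], []
    for s in seeds:
        cfg = MrSimConfig(
            n_snps=28, beta_true=BETA_TRUE, pleiotropy_mode="directional",
            pleiotropy_sd=0.01, pleiotropy_frac=0.3, seed=int(s),
        )
        e, o, *_ = gen_mr_dataset(cfg)
        h = harmonize(e, o)
        med.append(weighted_median(h, n_boot=2, seed=int(s)).beta - BETA_TRUE)
        ivw_b.append(ivw(h).beta - BETA_TRUE)
    return {
        "median_abs_bias": float(abs(np.mean(med))),
        "ivw_abs_bias": float(abs(np.mean(ivw_b))),
        "n_reps": n_reps,
    }


def mrpresso_outlier_detection(n_reps: int = 200, n_sim: int = 500,
                               seed: int = 0) -> dict:
    """Rate at which a planted 10-sigma pleiotropic variant is flagged."""
    seeds = _sub_seeds(seed, n_reps)
    flagged = exact = 0
    for s in seeds:
        e, o, _, _, truth = gen_mr_dataset(
            MrSimConfig(n_snps=20, beta_true=BETA_TRUE, outlier_indices=(3,),
                        outlier_offset=10.0, seed=int(s))
        )
        h = harmonize(e, o)
        _, outl = mrpresso_outliers(h, n_sim=n_sim, seed=int(s))
        planted = truth.per_snp.loc[truth.per_snp["is_outlier"], "rsid"].iloc[0]
        flagged += planted in outl
        exact += outl == [planted]
    return {"detection_rate": flagged / n_reps, "exact_rate": exact / n_reps,
            "n_reps": n_reps, "n_sim": n_sim}


def mrpresso_null_uniformity(n_reps: int = 200, n_sim: int = 500,
                             seed: int = 0) -> dict:
    """KS test of the global p-value against Uniform(0,1) under the null."""
    seeds = _sub_seeds(seed, n_reps)
    ps = []
    for s in seeds:
        e, o, *_ = gen_mr_dataset(
            MrSimConfig(n_snps=20, beta_true=BETA_TRUE, seed=int(s))
        )
        _, p = mrpresso_global(harmonize(e, o), n_sim=n_sim, seed=int(s))
        ps.append(p)
    return {"ks_pvalue": float(stats.kstest(ps, "uniform").pvalue),
            "n_reps": n_reps, "n_sim": n_sim}


def harmonization_recovery(seed: int = 0) -> dict:
    """Worst-case error of pipeline-recovered effect pairs vs the
    generator's pre-corruption truth, across heavily corrupted datasets."""
    seeds = _sub_seeds(seed, 20)
    worst = 0.0
    lost = 0
    for s in seeds:
        cfg = MrSimConfig(
            n_snps=28, beta_true=BETA_TRUE, frac_strand_flip=0.2,
            frac_allele_swap=0.2, frac_palindromic=0.25, seed=int(s),
        )
        e, o, _, _, truth = gen_mr_dataset(cfg)
        h = harmonize(e, o)
        t = truth.per_snp.set_index("rsid")
        got = h.df.set_index("rsid")
        lost += 28 - len(got)
        worst = max(
            worst,
            float(np.max(np.abs(got["gamma"] - t.loc[got.index, "gamma_oriented"]))),
            float(np.max(np.abs(got["Gamma"] - t.loc[got.index, "Gamma_oriented"]))),
        )
    return {"max_abs_error": worst, "n_snps_lost": lost, "n_datasets": len(seeds)}


def clump_brute_force_check(seed: int = 0) -> dict:
    """Exhaustive pairwise verification of greedy LD clumping output."""
    seeds = _sub_seeds(seed, 10)
    violations = unexplained = 0
    for s in seeds:
        cfg = MrSimConfig(n_snps=50, ld_block_size=5, ld_within_r2=0.6, seed=int(s))
        exposure, _, _, ld, _ = gen_mr_dataset(cfg)
        kept = ld_clump(exposure, ld)
        kept_ids = set(kept.rsids)
        df = exposure.df.set_index("rsid")

        def conflict(a, b):
            if str(df.loc[a, "chrom"]) != str(df.loc[b, "chrom"]):
                return False
            if abs(int(df.loc[a, "pos"]) - int(df.loc[b, "pos"])) > 1_000_000:
                return False
            r2 = ld.lookup(a, b)
            return r2 is not None and r2 >= 0.2

        for a in kept_ids:
            for b in kept_ids:
                if a < b and conflict(a, b):
                    violations += 1
        for r in set(exposure.rsids) - kept_ids:
            if not any(
                conflict(r, k) and (df.loc[k, "pvalue"], k) < (df.loc[r, "pvalue"], r)
                for k in kept_ids
            ):
                unexplained += 1
    return {"retained_pair_violations": violations,
            "unexplained_removals": unexplained, "n_datasets": len(seeds)}


def meta_parameter_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Bias of the DL pooled estimate on 21-study corpora (mu = ln 1.16,
    tau = 0.05), plus the mean heterogeneity the pooling reports."""
    seeds = _sub_seeds(seed, n_reps)
    mus, i2s = [], []
    for s in seeds:
        recs, _ = gen_meta_studies(
            MetaSimConfig(k_studies=21, mu_true=MU_TRUE, tau=0.05, seed=int(s))
        )
        res = pool_studies(recs)
        mus.append(res.pooled_log)
        i2s.append(res.i2_percent)
    mus = np.asarray(mus)
    mc_se = float(np.std(mus, ddof=1) / np.sqrt(n_reps))
    return {
        "mean_pooled_log": float(np.mean(mus)),
        "mu_true": MU_TRUE,
        "abs_bias": float(abs(np.mean(mus) - MU_TRUE)),
        "mc_se": mc_se,
        "mean_pooled_rr": float(np.exp(np.mean(mus))),
        "mean_i2_percent": float(np.mean(i2s)),
        "n_reps": n_reps,
    }


def meta_i2_monotone(seed: int = 0, taus=(0.0, 0.1, 0.2), n_reps: int = 200) -> dict:
    """Mean reported I2 across a grid of generated between-study SDs."""
    out = []
    for j, tau in enumerate(taus):
        seeds = _sub_seeds(seed + j, n_reps)
        i2s = [
            pool_studies(
                gen_meta_studies(
                    MetaSimConfig(k_studies=21, mu_true=MU_TRUE, tau=tau, seed=int(s))
                )[0]
            ).i2_percent
            for s in seeds
        ]
        out.append(float(np.mean(i2s)))
    return {"taus": list(taus), "mean_i2": out, "n_reps": n_reps}


def meta_egger_bias_power(n_reps: int = 200, seed: int = 0,
                          bias_coefficient: float = 2.0) -> dict:
    """Power of the Egger regression test to detect a planted small-study
    effect (study means inflated proportionally to their SE) at k=20."""
    seeds = _sub_seeds(seed, n_reps)
    hits = 0
    for s in seeds:
        recs, _ = gen_meta_studies(
            MetaSimConfig(k_studies=20, mu_true=MU_TRUE, tau=0.05,
                          small_study_bias=bias_coefficient, seed=int(s))
        )
        hits += egger_bias_test(recs)[2] < 0.05
    return {"power": hits / n_reps, "bias_coefficient": bias_coefficient,
            "n_reps": n_reps}
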