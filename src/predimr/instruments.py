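"""Exposure-only instrument construction.

The instrument set for a glycaemic exposure is built in four stages:

1. genome-wide significance filter on the exposure GWAS (P < 5e-8, strict);
2. exclusion of variants nominally associated with diabetes in an
   independent disease GWAS (retain P > 0.05, strict) — this is what makes
   the instrument reflect *nondiabetic* glycaemic variation rather than
   diabetes itself;
3. greedy LD clumping (r2 < 0.2 within a 1000 kb window, lowest p wins)
   so retained instruments are approximately independent;
4. harmonization of exposure and outcome records onto the same effect
   allele, resolving strand flips and palindromic A/T / C/G variants.

Variants absent from the disease GWAS cannot be certified as
disease-free and are dropped (logged separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    LdMatrix,
    SummaryStatSet,
    classify_palindromic,
    _COMPLEMENT,
)

__all__ = [
    "HarmonizedInstrumentSet",
    "HarmonizationError",
    "select_significant",
    "exclude_disease_associated",
    "ld_clump",
    "harmonize",
]

HARMONIZED_COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "gamma",
    "se_x",
    "Gamma",
    "se_y",
    "eaf_x",
    "eaf_y",
]

Action = Literal[
    "kept",
    "sign_flipped",
    "palindrome_aligned",
    "dropped_palindrome",
    "dropped_mismatch",
    "dropped_missing",
]


class HarmonizationError(ValueError):
    pass


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP exposure/outcome effect pairs ready for estimation.

    ``df`` holds one row per retained instrument with exposure effect
    ``gamma`` (oriented positive), its SE ``se_x``, outcome effect
    ``Gamma`` on the same allele, SE ``se_y`` and the effect-allele
    frequencies in each GWAS. ``log`` records the action taken for every
    candidate SNP, retained or not.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    log: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["rsid", "action"]))

    def __post_init__(self) -> None:
        self.df = self.df[HARMONIZED_COLUMNS].reset_index(drop=True)
        if (self.df["se_x"] <= 0).any() or (self.df["se_y"] <= 0).any():
            raise HarmonizationError("all standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, se_x, Gamma, se_y) as float arrays."""
        d = self.df
        return (
            d["gamma"].to_numpy(float),
            d["se_x"].to_numpy(float),
            d["Gamma"].to_numpy(float),
            d["se_y"].to_numpy(float),
        )

    def drop(self, rsids: list[str]) -> "HarmonizedInstrumentSet":
        keep = ~self.df["rsid"].isin(set(rsids))
        return HarmonizedInstrumentSet(
            self.exposure_id, self.outcome_id, self.df[keep].copy(), self.log
        )

    def to_summary_stat_sets(self) -> tuple[SummaryStatSet, SummaryStatSet]:
        """Re-express the harmonized pairs as two canonical summary sets.

        p-values are recomputed from the z-scores (two-sided normal); used
        mainly to check that harmonization is idempotent.
        """
        base = self.df[["rsid", "effect_allele", "other_allele"]].copy()
        exp = base.copy()
        exp["beta"], exp["se"], exp["eaf"] = self.df["gamma"], self.df["se_x"], self.df["eaf_x"]
        out = base.copy()
        out["beta"], out["se"], out["eaf"] = self.df["Gamma"], self.df["se_y"], self.df["eaf_y"]
        for d in (exp, out):
            z = np.abs(d["beta"] / d["se"])
            d["pvalue"] = np.clip(2 * stats.norm.sf(z), np.nextafter(0, 1), 1.0)
        return (
            SummaryStatSet(self.exposure_id, exp),
            SummaryStatSet(self.outcome_id, out),
        )


def select_significant(
    exposure: SummaryStatSet, p_threshold: float = 5e-8
) -> SummaryStatSet:
    """Retain variants with p strictly below the genome-wide threshold."""
    keep = exposure.df[exposure.df["pvalue"] < p_threshold].copy()
    return SummaryStatSet(exposure.trait_id, keep, exposure.trait_type, exposure.unit)


def exclude_disease_associated(
    candidates: SummaryStatSet,
    disease: SummaryStatSet,
    p_exclusion: float = 0.05,
) -> tuple[SummaryStatSet, dict]:
    """Drop candidates nominally associated with the disease GWAS.

    A candidate is retained only if its disease p-value is strictly above
    ``p_exclusion``. Candidates absent from the disease set cannot be
    certified non-associated and are dropped too (reported separately).
    """
    disease_p = dict(zip(disease.df["rsid"], disease.df["pvalue"]))
    kept, excluded, missing = [], [], []
    for rsid, p in zip(candidates.df["rsid"], candidates.df["pvalue"]):
        dp = disease_p.get(rsid)
        if dp is None:
            missing.append(rsid)
        elif dp > p_exclusion:
            kept.append(rsid)
        else:
            excluded.append(rsid)
    report = {
        "n_candidates": candidates.n_snps,
        "kept": kept,
        "excluded_associated": excluded,
        "excluded_missing_from_disease": missing,
    }
    return candidates.subset(kept), report


def ld_clump(
    candidates: SummaryStatSet,
    ld: LdMatrix,
    r2_threshold: float = 0.2,
    window_kb: float = 1000.0,
) -> SummaryStatSet:
    """Greedy LD clumping: lowest p-value wins, correlated neighbours go.

    Candidates are visited in ascending p-value order (ties broken by
    rsid); each accepted variant removes remaining variants on the same
    chromosome within ``window_kb`` whose r2 with it is >= ``r2_threshold``.
    Variants missing from the LD matrix, or lacking position information,
    are treated as independent. Cross-chromosome pairs never clump.
    """
    df = candidates.df.sort_values(["pvalue", "rsid"], kind="mergesort")
    window_bp = window_kb * 1000.0
    accepted: list[str] = []
    removed: set[str] = set()
    rows = list(df.itertuples(index=False))
    for i, row in enumerate(rows):
        if row.rsid in removed:
            continue
        accepted.append(row.rsid)
        if pd.isna(row.chrom) or pd.isna(row.pos):
            continue
        for other in rows[i + 1 :]:
            if other.rsid in removed:
                continue
            if pd.isna(other.chrom) or pd.isna(other.pos):
                continue
            if str(other.chrom) != str(row.chrom):
                continue
            if abs(float(other.pos) - float(row.pos)) > window_bp:
                continue
            r2 = ld.lookup(row.rsid, other.rsid)
            if r2 is not None and r2 >= r2_threshold:
                removed.add(other.rsid)
    return candidates.subset(accepted)


def _complement_pair(a1: str, a2: str) -> tuple[str, str] | None:
    if len(a1) == 1 and len(a2) == 1 and a1 in _COMPLEMENT and a2 in _COMPLEMENT:
        return _COMPLEMENT[a1], _COMPLEMENT[a2]
    return None


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_policy: Literal["infer", "drop"] = "infer",
    eaf_ambiguity: float = 0.42,
) -> HarmonizedInstrumentSet:
    """Align outcome effects onto the exposure effect allele per variant.

    For each exposure instrument found in the outcome set:

    * identical alleles — keep as-is;
    * swapped alleles — flip the outcome effect sign, mirror its frequency;
    * strand complements (plain or swapped) — complement, then as above;
    * palindromic (A/T, C/G) — strand is unresolvable from alleles; with
      ``policy="infer"``, align by allele frequency (both sides of 0.5
      agree → keep, disagree → flip) unless either frequency is missing
      or inside the ambiguity band ``[eaf_ambiguity, 1 - eaf_ambiguity]``,
      in which case drop; with ``policy="drop"``, always drop;
    * irreconcilable alleles or absent from the outcome — drop.

    Finally every exposure effect is oriented positive (flipping gamma,
    Gamma and both frequencies together), which leaves ratio-based
    estimators untouched and makes the Egger regression identifiable.
    """
    out_by_rsid = {r: row for r, row in zip(outcome.df["rsid"], outcome.df.itertuples(index=False))}
    rows: list[dict] = []
    log: list[tuple[str, str]] = []

    for erow in exposure.df.itertuples(index=False):
        rsid = erow.rsid
        orow = out_by_rsid.get(rsid)
        if orow is None:
            log.append((rsid, "dropped_missing"))
            continue
        e1, e2 = erow.effect_allele, erow.other_allele
        o1, o2 = orow.effect_allele, orow.other_allele
        eaf_x = None if pd.isna(erow.eaf) else float(erow.eaf)
        eaf_y = None if pd.isna(orow.eaf) else float(orow.eaf)
        Gamma, se_y = float(orow.beta), float(orow.se)

        if classify_palindromic(e1, e2):
            if {o1, o2} != {e1, e2}:
                log.append((rsid, "dropped_mismatch"))
                continue
            if palindrome_policy == "drop":
                log.append((rsid, "dropped_palindrome"))
                continue
            lo, hi = eaf_ambiguity, 1.0 - eaf_ambiguity
            if (
                eaf_x is None
                or eaf_y is None
                or lo <= eaf_x <= hi
                or lo <= eaf_y <= hi
            ):
                log.append((rsid, "dropped_palindrome"))
                continue
            # nominal allele alignment first, then frequency check
            if o1 == e2:
                Gamma, eaf_y = -Gamma, 1.0 - eaf_y
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                Gamma, eaf_y = -Gamma, 1.0 - eaf_y
            action = "palindrome_aligned"
        else:
            comp = _complement_pair(o1, o2)
            if (o1, o2) == (e1, e2):
                action = "kept"
            elif (o1, o2) == (e2, e1):
                Gamma = -Gamma
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
                action = "sign_flipped"
            elif comp is not None and comp == (e1, e2):
                action = "kept"
            elif comp is not None and comp == (e2, e1):
                Gamma = -Gamma
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
                action = "sign_flipped"
            else:
                log.append((rsid, "dropped_mismatch"))
                continue

        gamma, se_x = float(erow.beta), float(erow.se)
        a1, a2 = e1, e2
        if gamma < 0:
            gamma, Gamma = -gamma, -Gamma
            a1, a2 = a2, a1
            eaf_x = None if eaf_x is None else 1.0 - eaf_x
            eaf_y = None if eaf_y is None else 1.0 - eaf_y
        log.append((rsid, action))
        rows.append(
            dict(
                rsid=rsid,
                effect_allele=a1,
                other_allele=a2,
                gamma=gamma,
                se_x=se_x,
                Gamma=Gamma,
                se_y=se_y,
                eaf_x=np.nan if eaf_x is None else eaf_x,
                eaf_y=np.nan if eaf_y is None else eaf_y,
            )
        )

    if not rows:
        raise HarmonizationError(
            f"harmonization of {exposure.trait_id} vs {outcome.trait_id} "
            "retained no variants"
        )
    return HarmonizedInstrumentSet(
        exposure.trait_id,
        outcome.trait_id,
        pd.DataFrame(rows),
        pd.DataFrame(log, columns=["rsid", "action"]),
    )
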