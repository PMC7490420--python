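"""Random-effects meta-analysis of observational risk estimates.

Study-level effect estimates (RR, OR or HR with 95% CIs) are moved to the
log scale, pooled with the DerSimonian–Laird random-effects model, and
probed with the standard battery: Cochran's Q and I² heterogeneity,
subgroup pooling, leave-one-study-out sensitivity, and Begg's rank
correlation and Egger's regression tests for small-study (publication)
bias.

Hazard ratios are pooled as-is with relative risks; odds ratios are
optionally converted to RRs via the baseline-risk formula
``RR = OR / (1 - p0 + p0*OR)`` when a baseline risk is available
(conversion is off by default since most study reports omit p0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "StudyRecord",
    "MetaResult",
    "MetaError",
    "to_log_effect",
    "dl_pool",
    "subgroup_pool",
    "leave_one_study_out",
    "egger_bias_test",
    "begg_bias_test",
    "funnel_table",
    "read_study_table",
]

#: Normal 97.5% quantile used to back-convert 95% CIs into standard errors.
Z95 = 1.959964


class MetaError(ValueError):
    pass


@dataclass(frozen=True)
class StudyRecord:
    """One observational study's ratio-scale effect estimate."""

    study_id: str
    effect_measure: str  # RR | OR | HR
    estimate: float
    ci_low: float
    ci_high: float
    outcome: str = ""
    labels: dict | None = None  # subgroup labels, e.g. {"definition": "IFG-ADA"}
    baseline_risk: float | None = None

    def __post_init__(self) -> None:
        if self.effect_measure not in ("RR", "OR", "HR"):
            raise MetaError(f"unknown effect measure '{self.effect_measure}'")
        if not (self.estimate > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise MetaError(f"{self.study_id}: effect and CI must be positive")
        if not (self.ci_low < self.estimate < self.ci_high):
            raise MetaError(f"{self.study_id}: CI must strictly bracket the estimate")
        if self.baseline_risk is not None and not (0 < self.baseline_risk < 1):
            raise MetaError(f"{self.study_id}: baseline risk must be in (0, 1)")


@dataclass(frozen=True)
class MetaResult:
    """A pooled random-effects result with heterogeneity statistics."""

    k: int
    pooled_log: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    Q: float | None
    p_Q: float | None
    i2_percent: float
    tau2: float

    @property
    def pooled_ratio(self) -> float:
        return float(np.exp(self.pooled_log))

    @property
    def ratio_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        lo, hi = self.ratio_ci
        return dict(
            k=self.k,
            pooled_log=self.pooled_log,
            se=self.se,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            pvalue=self.pvalue,
            pooled_ratio=self.pooled_ratio,
            ratio_ci_low=lo,
            ratio_ci_high=hi,
            Q=self.Q,
            p_Q=self.p_Q,
            i2_percent=self.i2_percent,
            tau2=self.tau2,
        )


def to_log_effect(
    record: StudyRecord, convert_or_to_rr: bool = False
) -> tuple[float, float]:
    """Log effect and its variance from a ratio-scale report.

    y = ln(estimate); se = (ln ci_high - ln ci_low) / (2 * 1.959964).
    With ``convert_or_to_rr`` and a baseline risk p0, an OR is first
    converted: RR = OR / (1 - p0 + p0*OR) (the CI bounds likewise).
    """
    est, lo, hi = record.estimate, record.ci_low, record.ci_high
    if convert_or_to_rr and record.effect_measure == "OR" and record.baseline_risk is not None:
        p0 = record.baseline_risk
        est, lo, hi = (x / (1 - p0 + p0 * x) for x in (est, lo, hi))
    y = float(np.log(est))
    se = float((np.log(hi) - np.log(lo)) / (2 * Z95))
    if se <= 0:
        raise MetaError(f"{record.study_id}: degenerate confidence interval")
    return y, se**2


def dl_pool(effects: Sequence[tuple[float, float]]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of (y, v) pairs.

    Moment estimator: with fixed weights w = 1/v,
    tau² = max(0, (Q - df) / (S1 - S2/S1)), S1 = sum(w), S2 = sum(w²);
    random-effects weights are 1/(v + tau²). I² = max(0, (Q - df)/Q)*100.
    A single study is returned as-is with Q reported absent.
    """
    if len(effects) == 0:
        raise MetaError("cannot pool zero studies")
    y = np.array([e[0] for e in effects], dtype=float)
    v = np.array([e[1] for e in effects], dtype=float)
    if np.any(v <= 0):
        raise MetaError("all variances must be positive")
    k = y.size
    if k == 1:
        se = float(np.sqrt(v[0]))
        return MetaResult(
            k=1,
            pooled_log=float(y[0]),
            se=se,
            ci_low=float(y[0] - Z95 * se),
            ci_high=float(y[0] + Z95 * se),
            pvalue=float(2 * stats.norm.sf(abs(y[0]) / se)),
            Q=None,
            p_Q=None,
            i2_percent=0.0,
            tau2=0.0,
        )
    w = 1.0 / v
    mu_f = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_f) ** 2))
    df = k - 1
    s1, s2 = float(np.sum(w)), float(np.sum(w**2))
    tau2 = max(0.0, (Q - df) / (s1 - s2 / s1))
    i2 = 0.0 if Q == 0 else max(0.0, (Q - df) / Q) * 100.0
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(np.sqrt(1.0 / np.sum(w_re)))
    return MetaResult(
        k=k,
        pooled_log=mu,
        se=se,
        ci_low=mu - Z95 * se,
        ci_high=mu + Z95 * se,
        pvalue=float(2 * stats.norm.sf(abs(mu) / se)),
        Q=Q,
        p_Q=float(stats.chi2.sf(Q, df)),
        i2_percent=float(i2),
        tau2=float(tau2),
    )


def _effects(records: Sequence[StudyRecord], convert_or_to_rr: bool = False):
    return [to_log_effect(r, convert_or_to_rr) for r in records]


def pool_studies(
    records: Sequence[StudyRecord], convert_or_to_rr: bool = False
) -> MetaResult:
    """Convenience: log-transform then DL-pool a sequence of study records."""
    return dl_pool(_effects(records, convert_or_to_rr))


def subgroup_pool(
    records: Sequence[StudyRecord], label_key: str
) -> dict[str, MetaResult]:
    """DL pooling within each level of a subgroup label, plus overall.

    The overall pool is stored under the key ``"(overall)"``.
    """
    groups: dict[str, list[StudyRecord]] = {}
    for r in records:
        if not r.labels or label_key not in r.labels:
            raise MetaError(f"{r.study_id}: no label '{label_key}'")
        groups.setdefault(str(r.labels[label_key]), []).append(r)
    out = {label: pool_studies(rs) for label, rs in sorted(groups.items())}
    out["(overall)"] = pool_studies(records)
    return out


def leave_one_study_out(
    records: Sequence[StudyRecord],
) -> list[tuple[str, MetaResult]]:
    """Pooled result omitting each study in turn, plus the full pool.

    The full pool is listed first under the id ``"(none)"``.
    """
    if len(records) < 2:
        raise MetaError("leave-one-study-out needs >= 2 studies")
    out = [("(none)", pool_studies(records))]
    for i in range(len(records)):
        reduced = [r for j, r in enumerate(records) if j != i]
        out.append((records[i].study_id, pool_studies(reduced)))
    return out


def egger_bias_test(records: Sequence[StudyRecord]) -> tuple[float, float, float]:
    """Egger's regression test for small-study effects.

    Regresses the standard normal deviate y/se on precision 1/se; the
    intercept estimates funnel asymmetry and is t-tested with k-2 df.
    Returns (intercept, se, p).
    """
    eff = _effects(records)
    k = len(eff)
    if k < 3:
        raise MetaError("Egger bias test needs >= 3 studies")
    y = np.array([e[0] for e in eff])
    se = np.sqrt([e[1] for e in eff])
    X = sm.add_constant(1.0 / se)
    fit = sm.OLS(y / se, X).fit()
    return float(fit.params[0]), float(fit.bse[0]), float(fit.pvalues[0])


def begg_bias_test(records: Sequence[StudyRecord]) -> tuple[float, float]:
    """Begg & Mazumdar rank-correlation test for publication bias.

    Kendall correlation between variance-standardized deviates
    u_i = (y_i - mu_F)/sqrt(v_i - 1/sum(w)) and the variances v_i, with
    the tie-corrected normal approximation for the p-value. Counting of
    concordant/discordant pairs is explicit over all C(k,2) pairs.
    """
    eff = _effects(records)
    k = len(eff)
    if k < 3:
        raise MetaError("Begg bias test needs >= 3 studies")
    y = np.array([e[0] for e in eff])
    v = np.array([e[1] for e in eff])
    w = 1.0 / v
    mu_f = np.sum(w * y) / np.sum(w)
    vstar = v - 1.0 / np.sum(w)
    eps = 1e-12
    if np.any(vstar <= eps):
        vstar = np.maximum(vstar, eps)
    u = (y - mu_f) / np.sqrt(vstar)

    conc = disc = 0
    ties_u = ties_v = 0
    for i in range(k):
        for j in range(i + 1, k):
            du, dv = u[i] - u[j], v[i] - v[j]
            if du == 0:
                ties_u += 1
            if dv == 0:
                ties_v += 1
            s = du * dv
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    n_pairs = k * (k - 1) // 2
    denom = np.sqrt((n_pairs - ties_u) * (n_pairs - ties_v))
    tau = (conc - disc) / denom if denom > 0 else 0.0

    var_z = k * (k - 1) * (2 * k + 5) / 18.0
    # tie correction on the variance of S = conc - disc
    for t_count in _tie_sizes(u) + _tie_sizes(v):
        var_z -= t_count * (t_count - 1) * (2 * t_count + 5) / 18.0
    if var_z <= 0:
        return float(tau), 1.0
    z = (conc - disc) / np.sqrt(var_z)
    return float(tau), float(2 * stats.norm.sf(abs(z)))


def _tie_sizes(x: np.ndarray) -> list[int]:
    _, counts = np.unique(x, return_counts=True)
    return [int(c) for c in counts if c > 1]


def funnel_table(
    records: Sequence[StudyRecord], result: MetaResult
) -> pd.DataFrame:
    """Per-study (y, se) table with the pooled reference, ordered by se."""
    rows = []
    for r in records:
        y, v = to_log_effect(r)
        rows.append(dict(study_id=r.study_id, y=y, se=float(np.sqrt(v)), pooled=result.pooled_log))
    return (
        pd.DataFrame(rows)
        .sort_values(["se", "study_id"], kind="mergesort")
        .reset_index(drop=True)
    )


STUDY_COLUMNS = ["study_id", "effect_measure", "estimate", "ci_low", "ci_high", "outcome"]


def read_study_table(path: str | Path) -> list[StudyRecord]:
    """Read study records from a TSV with header.

    Required columns: study_id, effect_measure, estimate, ci_low, ci_high.
    Optional: outcome, baseline_risk; any other column becomes a subgroup
    label.
    """
    df = pd.read_csv(path, sep="\t")
    required = STUDY_COLUMNS[:5]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MetaError(f"study table missing columns: {missing}")
    label_cols = [c for c in df.columns if c not in STUDY_COLUMNS + ["baseline_risk"]]
    out = []
    for row in df.to_dict("records"):
        out.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                effect_measure=str(row["effect_measure"]),
                estimate=float(row["estimate"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                outcome=str(row.get("outcome", "") or ""),
                labels={c: row[c] for c in label_cols} or None,
                baseline_risk=(
                    float(row["baseline_risk"])
                    if "baseline_risk" in row and pd.notna(row.get("baseline_risk"))
                    else None
                ),
            )
        )
    return out


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> Path:
    path = Path(path)
    label_keys = sorted({k for r in records if r.labels for k in r.labels})
    with open(path, "wt") as fh:
        fh.write("\t".join(STUDY_COLUMNS + label_keys) + "\n")
        for r in records:
            cells = [
                r.study_id,
                r.effect_measure,
                repr(float(r.estimate)),
                repr(float(r.ci_low)),
                repr(float(r.ci_high)),
                r.outcome,
            ]
            cells += [str((r.labels or {}).get(k, "")) for k in label_keys]
            fh.write("\t".join(cells) + "\n")
    return path
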