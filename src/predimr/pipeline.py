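"""Orchestration of the two analysis arms from a declarative config.

The MR arm chains instrument construction (significance filter → disease
exclusion → LD clumping → harmonization) into the estimator battery
(plain/robust IVW, plain/robust Egger, weighted median, Cochran's Q,
MR-PRESSO when enough SNPs remain, leave-one-out). The meta arm pools an
observational study table overall, per outcome and per subgroup, with
leave-one-study-out and publication-bias tests. Both emit a single
:class:`AnalysisReport` rendered as JSON plus TSV tables.

Every stochastic step records its seed and replicate count in the report,
and re-running with the same config reproduces every number exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import instruments, meta, sumstats
from .estimators import (
    EstimationError,
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    weighted_median,
)
from .mrpresso import run_mrpresso

__all__ = ["AnalysisConfig", "AnalysisReport", "run_mr_arm", "run_meta_arm", "render_report"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Declarative settings for one analysis run (YAML-loadable)."""

    # MR arm inputs
    exposure_path: str | None = None
    exposure_columns: dict | str = "magic"
    outcome_path: str | None = None
    outcome_columns: dict | str = "cardiogram"
    disease_path: str | None = None
    disease_columns: dict | str = "magic"
    ld_path: str | None = None
    # instrument thresholds
    p_threshold: float = 5e-8
    p_exclusion: float = 0.05
    r2_threshold: float = 0.2
    window_kb: float = 1000.0
    palindrome_policy: str = "infer"
    eaf_ambiguity: float = 0.42
    # estimation
    methods: tuple[str, ...] = (
        "ivw_robust",
        "ivw",
        "egger_robust",
        "egger",
        "weighted_median",
    )
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    ancestry_label: str = "European"
    # meta arm inputs
    meta_path: str | None = None
    subgroup_keys: tuple[str, ...] = ()
    # output
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods", "subgroup_keys"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Structured results of one run; serialises to JSON/TSV."""

    config: dict = field(default_factory=dict)
    instrument_log: dict = field(default_factory=dict)
    mr_estimates: list[dict] = field(default_factory=list)
    heterogeneity: dict = field(default_factory=dict)
    mrpresso: dict | None = None
    leave_one_out: list[dict] = field(default_factory=list)
    scatter: list[dict] = field(default_factory=list)
    meta_results: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(
            config=self.config,
            instrument_log=self.instrument_log,
            mr_estimates=self.mr_estimates,
            heterogeneity=self.heterogeneity,
            mrpresso=self.mrpresso,
            leave_one_out=self.leave_one_out,
            scatter=self.scatter,
            meta_results=self.meta_results,
            errors=self.errors,
        )


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def build_instruments(
    exposure: sumstats.SummaryStatSet,
    outcome: sumstats.SummaryStatSet,
    disease: sumstats.SummaryStatSet,
    ld: sumstats.LdMatrix,
    config: AnalysisConfig,
) -> tuple[instruments.HarmonizedInstrumentSet, dict]:
    """Run the four construction stages, accounting for counts at each."""
    log: dict[str, Any] = {"n_exposure_snps": exposure.n_snps}

    sig = instruments.select_significant(exposure, config.p_threshold)
    log["n_significant"] = sig.n_snps
    if sig.n_snps == 0:
        raise StageError("significance filter retained no SNPs")

    nond, excl_report = instruments.exclude_disease_associated(sig, disease, config.p_exclusion)
    log["n_after_disease_exclusion"] = nond.n_snps
    log["disease_exclusion"] = {
        k: (len(v) if isinstance(v, list) else v) for k, v in excl_report.items()
    }
    if nond.n_snps == 0:
        raise StageError("disease-association exclusion retained no SNPs")

    clumped = instruments.ld_clump(nond, ld, config.r2_threshold, config.window_kb)
    log["n_after_clumping"] = clumped.n_snps

    try:
        harm = instruments.harmonize(
            clumped, outcome, config.palindrome_policy, config.eaf_ambiguity
        )
    except instruments.HarmonizationError as exc:
        raise StageError(f"harmonization: {exc}") from exc
    log["n_harmonized"] = harm.n_snps
    log["harmonization_actions"] = harm.log["action"].value_counts().to_dict()
    log["stage_counts"] = (
        f"{exposure.n_snps} -> {sig.n_snps} -> {nond.n_snps} -> "
        f"{clumped.n_snps} -> {harm.n_snps}"
    )
    return harm, log


def run_mr_arm(
    config: AnalysisConfig,
    data: tuple | None = None,
) -> AnalysisReport:
    """Execute the MR arm end to end.

    ``data`` may supply in-memory (exposure, outcome, disease, ld) sets;
    otherwise the paths in the config are loaded.
    """
    if data is None:
        if not (config.exposure_path and config.outcome_path and config.disease_path):
            raise StageError("input: exposure, outcome and disease paths are required")
        exposure, _ = sumstats.read_summary_stats(
            config.exposure_path, config.exposure_columns, "exposure"
        )
        outcome, _ = sumstats.read_summary_stats(
            config.outcome_path, config.outcome_columns, "outcome", "binary"
        )
        disease, _ = sumstats.read_summary_stats(
            config.disease_path, config.disease_columns, "disease", "binary"
        )
        if config.ld_path:
            ld = sumstats.read_ld_table(config.ld_path)
        else:  # no LD information: treat all variants as independent
            import numpy as np

            ld = sumstats.LdMatrix(exposure.rsids, np.eye(exposure.n_snps))
    else:
        exposure, outcome, disease, ld = data

    report = AnalysisReport(config=_config_dict(config))
    harm, report.instrument_log = build_instruments(exposure, outcome, disease, ld, config)

    for method in config.methods:
        try:
            if method in ("ivw", "ivw_robust"):
                est = ivw(harm, robust=method.endswith("robust")).to_dict()
            elif method in ("egger", "egger_robust"):
                est = mr_egger(harm, robust=method.endswith("robust")).to_dict()
            elif method == "weighted_median":
                est = weighted_median(harm, n_boot=config.n_boot, seed=config.seed).to_dict()
                est.update(n_boot=config.n_boot, seed=config.seed)
            else:
                raise EstimationError(f"unknown method '{method}'")
            report.mr_estimates.append(est)
        except EstimationError as exc:
            report.errors[method] = str(exc)
            logger.warning("method %s failed: %s", method, exc)

    ivw_beta = next(
        (e["beta"] for e in report.mr_estimates if e["method"] == "ivw"),
        next((e["beta"] for e in report.mr_estimates), None),
    )
    if ivw_beta is not None and harm.n_snps >= 2:
        q, df, p = cochran_q(harm, ivw_beta)
        report.heterogeneity = dict(Q=q, df=df, pvalue=p)

    if harm.n_snps >= 4:
        presso = run_mrpresso(harm, n_sim=config.n_sim, seed=config.seed)
        report.mrpresso = presso.to_dict()
        loo = leave_one_out(harm, method="ivw_robust")
        report.leave_one_out = loo.rows()
    else:
        report.errors["mrpresso"] = (
            f"skipped: needs >= 4 SNPs, got {harm.n_snps}"
        )
        report.errors["leave_one_out"] = report.errors["mrpresso"]

    z = meta.Z95
    for row in harm.df.itertuples(index=False):
        report.scatter.append(
            dict(
                rsid=row.rsid,
                gamma=row.gamma,
                gamma_ci_low=row.gamma - z * row.se_x,
                gamma_ci_high=row.gamma + z * row.se_x,
                Gamma=row.Gamma,
                Gamma_ci_low=row.Gamma - z * row.se_y,
                Gamma_ci_high=row.Gamma + z * row.se_y,
            )
        )
    return report


def run_meta_arm(
    config: AnalysisConfig,
    records: list[meta.StudyRecord] | None = None,
) -> AnalysisReport:
    """Execute the observational arm: pooling, subgroups, sensitivity, bias."""
    if records is None:
        if not config.meta_path:
            raise StageError("input: meta_path is required")
        records = meta.read_study_table(config.meta_path)

    report = AnalysisReport(config=_config_dict(config))
    outcomes = sorted({r.outcome for r in records})
    for outcome_label in outcomes:
        group = [r for r in records if r.outcome == outcome_label]
        entry: dict[str, Any] = {}
        try:
            pooled = meta.pool_studies(group)
            entry["pooled"] = pooled.to_dict()
            if len(group) >= 2:
                entry["leave_one_study_out"] = [
                    dict(omitted=sid, **res.to_dict())
                    for sid, res in meta.leave_one_study_out(group)
                ]
            if len(group) >= 3:
                b0, b_se, b_p = meta.egger_bias_test(group)
                tau_b, begg_p = meta.begg_bias_test(group)
                entry["egger_bias"] = dict(intercept=b0, se=b_se, pvalue=b_p)
                entry["begg_bias"] = dict(kendall_tau=tau_b, pvalue=begg_p)
            else:
                entry["bias_tests"] = f"skipped: needs >= 3 studies, got {len(group)}"
            entry["funnel"] = meta.funnel_table(group, pooled).to_dict("records")
            for key in config.subgroup_keys:
                entry.setdefault("subgroups", {})[key] = {
                    label: res.to_dict()
                    for label, res in meta.subgroup_pool(group, key).items()
                }
        except meta.MetaError as exc:
            report.errors[f"meta:{outcome_label}"] = str(exc)
            continue
        report.meta_results[outcome_label] = entry
    return report


def render_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the report as JSON plus TSV tables; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    json_path = out / "report.json"
    with open(json_path, "wt") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    written.append(json_path)

    if report.mr_estimates:
        p = out / "mr_estimates.tsv"
        pd.DataFrame(report.mr_estimates).to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.leave_one_out:
        p = out / "leave_one_out.tsv"
        pd.DataFrame(report.leave_one_out).to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.scatter:
        p = out / "scatter.tsv"
        pd.DataFrame(report.scatter).to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.meta_results:
        rows = []
        for outcome_label, entry in sorted(report.meta_results.items()):
            if "pooled" in entry:
                rows.append(dict(outcome=outcome_label, **entry["pooled"]))
        if rows:
            p = out / "meta_pooled.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)
    return written


def _config_dict(config: AnalysisConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
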