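"""Reading, validating and writing GWAS summary statistics and LD tables.

Summary statistics arrive as delimited text with heterogeneous headers
(each consortium uses its own dialect); a user-supplied column map — or one
of the shipped presets — renames them onto the canonical schema used
throughout the package:

    rsid, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue, n

``beta`` is the per-allele effect on the trait scale (log-odds for binary
traits), ``se`` its standard error, ``eaf`` the effect-allele frequency
(may be missing). Rows violating the record invariants are dropped, not
repaired, and accounted for in a :class:`LoadReport`.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpAssociation",
    "SummaryStatSet",
    "LdMatrix",
    "LoadReport",
    "COLUMN_PRESETS",
    "CANONICAL_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_table",
    "classify_palindromic",
]

CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Minimum columns a column map must provide.
REQUIRED_COLUMNS = ["rsid", "effect_allele", "other_allele", "beta", "se", "pvalue"]

#: Header presets for the dialects of the public files this pipeline targets.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    # MAGIC-style glycaemic trait files
    "magic": {
        "rsid": "snp",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "maf",
        "beta": "effect",
        "se": "stderr",
        "pvalue": "pvalue",
    },
    # CARDIoGRAMplusC4D / CAD_META-style
    "cardiogram": {
        "rsid": "oldID",
        "chrom": "CHR",
        "pos": "BP",
        "effect_allele": "Allele1",
        "other_allele": "Allele2",
        "eaf": "Freq1",
        "beta": "Effect",
        "se": "StdErr",
        "pvalue": "P-value",
    },
    # CKDGen-style
    "ckdgen": {
        "rsid": "RSID",
        "chrom": "Chr",
        "pos": "Pos_b37",
        "effect_allele": "Allele1",
        "other_allele": "Allele2",
        "eaf": "Freq1",
        "beta": "Effect",
        "se": "StdErr",
        "pvalue": "P-value",
        "n": "n_total_sum",
    },
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Raised on configuration or empty-input failures while loading."""


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association record in one GWAS."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    trait_id: str = ""

    def is_valid(self) -> bool:
        return not _invalid_reason(self)


def _invalid_reason(rec: SnpAssociation) -> str | None:
    if not rec.rsid:
        return "missing_rsid"
    if rec.effect_allele == rec.other_allele or not rec.effect_allele or not rec.other_allele:
        return "bad_alleles"
    if not np.isfinite(rec.beta):
        return "bad_beta"
    if not (np.isfinite(rec.se) and rec.se > 0):
        return "bad_se"
    if not (np.isfinite(rec.pvalue) and 0 < rec.pvalue <= 1):
        return "bad_pvalue"
    if rec.eaf is not None and not (0 <= rec.eaf <= 1):
        return "bad_eaf"
    return None


@dataclass
class LoadReport:
    """Accounting of what a loader kept and dropped."""

    path: str
    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    n_duplicates_collapsed: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SummaryStatSet:
    """A GWAS summary-statistic table on the canonical schema, unique by rsid."""

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "quantitative"  # or "binary"
    unit: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        for c in missing:
            self.df[c] = np.nan
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        if self.df["rsid"].duplicated().any():
            raise SumstatsError(f"duplicate rsids in SummaryStatSet '{self.trait_id}'")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])

    def subset(self, rsids: Sequence[str]) -> "SummaryStatSet":
        keep = self.df[self.df["rsid"].isin(set(rsids))].copy()
        return SummaryStatSet(self.trait_id, keep, self.trait_type, self.unit)

    def records(self) -> list[SnpAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                SnpAssociation(
                    rsid=row.rsid,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=row.beta,
                    se=row.se,
                    pvalue=row.pvalue,
                    chrom=None if pd.isna(row.chrom) else str(row.chrom),
                    pos=None if pd.isna(row.pos) else int(row.pos),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    n=None if pd.isna(row.n) else float(row.n),
                    trait_id=self.trait_id,
                )
            )
        return out


def classify_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}.

    Indels and multi-base alleles are never palindromic: strand ambiguity
    from reverse complementation is defined only for single-base pairs.
    """
    a, b = effect_allele.upper(), other_allele.upper()
    if len(a) != 1 or len(b) != 1:
        return False
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _validate_frame(df: pd.DataFrame, trait_id: str, report: LoadReport) -> pd.DataFrame:
    """Drop rows failing the record invariants, tallying reasons."""
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    # float() parses correctly rounded (pd.to_numeric's fast path does not,
    # which would break bit-exact round-trips)
    for col in ("beta", "se", "pvalue", "eaf", "pos", "n"):
        if col in df.columns:
            df[col] = df[col].map(_parse_float).astype(float)

    checks = {
        "missing_rsid": df["rsid"].isna() | (df["rsid"].astype(str) == ""),
        "bad_alleles": (df["effect_allele"] == df["other_allele"])
        | df["effect_allele"].isin(["", "NAN"])
        | df["other_allele"].isin(["", "NAN"]),
        "bad_beta": ~np.isfinite(df["beta"]),
        "bad_se": ~(np.isfinite(df["se"]) & (df["se"] > 0)),
        "bad_pvalue": ~(np.isfinite(df["pvalue"]) & (df["pvalue"] > 0) & (df["pvalue"] <= 1)),
    }
    if "eaf" in df.columns:
        eaf = df["eaf"]
        checks["bad_eaf"] = eaf.notna() & ~((eaf >= 0) & (eaf <= 1))

    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        newly = mask & ~bad
        n = int(newly.sum())
        if n:
            report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + n
        bad |= mask
    report.n_dropped += int(bad.sum())
    return df[~bad]


def _parse_float(x) -> float:
    if pd.isna(x):
        return np.nan
    try:
        return float(x)
    except (TypeError, ValueError):
        return np.nan


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | str,
    trait_id: str,
    trait_type: str = "quantitative",
    unit: str = "",
) -> tuple[SummaryStatSet, LoadReport]:
    """Load a delimited (optionally gzipped) summary-statistic file.

    ``column_map`` maps canonical names to file header names, or names one
    of :data:`COLUMN_PRESETS`. Rows violating the record invariants are
    dropped and counted; duplicate rsids are resolved by keeping the row
    with the smallest p-value.
    """
    if isinstance(column_map, str):
        try:
            column_map = COLUMN_PRESETS[column_map]
        except KeyError:
            raise SumstatsError(
                f"unknown column preset '{column_map}'; available: {sorted(COLUMN_PRESETS)}"
            ) from None
    missing_req = [c for c in REQUIRED_COLUMNS if c not in column_map]
    if missing_req:
        raise SumstatsError(f"column_map must provide {missing_req}")

    df = pd.read_csv(path, sep=r"\s+", dtype=str, compression="infer")
    df = df.mask(df.isin(["NA", ""]))
    missing_cols = [v for v in column_map.values() if v not in df.columns]
    if missing_cols:
        raise SumstatsError(f"mapped columns absent from {path}: {missing_cols}")

    df = df.rename(columns={v: k for k, v in column_map.items()})
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]

    report = LoadReport(path=str(path), n_rows=len(df))
    df = _validate_frame(df, trait_id, report)

    # duplicate rsids: keep the smallest p-value
    if df["rsid"].duplicated().any():
        before = len(df)
        df = df.sort_values(["pvalue", "rsid"], kind="mergesort").drop_duplicates(
            "rsid", keep="first"
        )
        report.n_duplicates_collapsed = before - len(df)
    df = df.sort_values("rsid", kind="mergesort").reset_index(drop=True)
    report.n_kept = len(df)

    if report.n_kept == 0:
        raise SumstatsError(f"no valid rows in {path}")
    return SummaryStatSet(trait_id, df, trait_type, unit), report


def write_summary_stats(sset: SummaryStatSet, path: str | Path) -> Path:
    """Write the canonical tab-delimited dialect (gzip if path ends .gz).

    ``read_summary_stats`` on the result with the identity column map
    reproduces the set (floats via repr round-trip, hence bit-exact for
    doubles).
    """
    path = Path(path)
    df = sset.df.copy()
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            cells = []
            for col, val in zip(CANONICAL_COLUMNS, row):
                if pd.isna(val):
                    cells.append("NA")
                elif col == "pos":
                    cells.append(str(int(val)))
                elif isinstance(val, float):
                    cells.append(repr(float(val)))
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")
    return path


CANONICAL_MAP = {c: c for c in CANONICAL_COLUMNS}


@dataclass
class LdMatrix:
    """Pairwise squared-correlation matrix over an ordered set of variants."""

    rsids: list[str]
    r2: np.ndarray
    pos: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise SumstatsError("LD matrix shape does not match rsid count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise SumstatsError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise SumstatsError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise SumstatsError("LD r2 entries must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}
        if len(self._index) != k:
            raise SumstatsError("duplicate rsids in LD matrix")

    def lookup(self, a: str, b: str) -> float | None:
        """r2 between two variants, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld_table(path: str | Path) -> LdMatrix:
    """Read a long-format LD table: rsid_a <TAB> rsid_b <TAB> r2.

    Missing pairs default to 0; the diagonal is set to 1.
    """
    tab = pd.read_csv(path, sep=r"\s+", header=0, dtype={0: str, 1: str})
    tab.columns = ["rsid_a", "rsid_b", "r2"]
    rsids = sorted(set(tab["rsid_a"]) | set(tab["rsid_b"]))
    idx = {r: i for i, r in enumerate(rsids)}
    m = np.zeros((len(rsids), len(rsids)))
    for a, b, r2 in tab.itertuples(index=False):
        m[idx[a], idx[b]] = r2
        m[idx[b], idx[a]] = r2
    np.fill_diagonal(m, 1.0)
    return LdMatrix(rsids, m)


def write_ld_table(ld: LdMatrix, path: str | Path) -> Path:
    """Write the upper triangle of an LD matrix in long format."""
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("rsid_a\trsid_b\tr2\n")
        k = len(ld.rsids)
        for i in range(k):
            for j in range(i + 1, k):
                if ld.r2[i, j] != 0.0:
                    fh.write(f"{ld.rsids[i]}\t{ld.rsids[j]}\t{repr(float(ld.r2[i, j]))}\n")
    return path
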