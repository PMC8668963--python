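"""Reading, writing and harmonizing GWAS summary statistics.

A :class:`GwasSummary` holds one trait's per-SNP association records
(alleles, effect-allele frequency, beta, SE, p-value, sample sizes).
:func:`harmonize` aligns an exposure instrument set with an outcome table,
producing a :class:`HarmonizedSet` whose rows and exclusion ledger partition
the input instruments — the bookkeeping that drives instrument accounting in
two-sample Mendelian randomization (missing SNPs, ambiguous palindromes,
incompatible allele pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit.summary_io")

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order for summary-statistic files.
CANONICAL_COLUMNS = (
    "SNP",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "ncase",
    "ncontrol",
)

MANDATORY_COLUMNS = ("SNP", "effect_allele", "other_allele", "beta", "se", "pval")

#: Exclusion reasons recorded by :func:`harmonize`.
REASON_MISSING = "missing_in_outcome"
REASON_PALINDROME = "palindromic_ambiguous"
REASON_INCOMPATIBLE = "incompatible_alleles"


class SummaryFormatError(ValueError):
    """A summary-statistic file is malformed (e.g. a mandatory column is absent)."""


class ValidationError(ValueError):
    """One or more records violate the summary-statistic invariants."""


class HarmonizationError(ValueError):
    """Harmonization produced no usable instrument rows."""


@dataclass
class GwasSummary:
    """One trait's GWAS summary statistics.

    ``records`` is a DataFrame with the canonical columns; betas are on the
    log-odds scale for binary traits and SD units for continuous traits.
    """

    trait_label: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.records = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        problems = _record_problems(self.records)
        if problems:
            raise ValidationError(
                f"invalid records in {self.trait_label!r}: " + "; ".join(problems[:5])
            )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, snp_ids: Sequence[str]) -> "GwasSummary":
        """Restrict to ``snp_ids``, preserving the given order."""
        idx = self.records.set_index("SNP")
        missing = [s for s in snp_ids if s not in idx.index]
        if missing:
            raise KeyError(f"SNPs not present in {self.trait_label!r}: {missing[:5]}")
        sub = idx.loc[list(snp_ids)].reset_index()
        return GwasSummary(self.trait_label, sub)


def _record_problems(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    dup = df["SNP"][df["SNP"].duplicated()]
    if len(dup):
        problems.append(f"duplicate snp_id {dup.iloc[0]!r}")
    for row in df.itertuples(index=False):
        bad = _row_problem(row)
        if bad:
            problems.append(bad)
    return problems


def _row_problem(row) -> str | None:
    if row.effect_allele not in VALID_ALLELES or row.other_allele not in VALID_ALLELES:
        return f"{row.SNP}: alleles must be single-nucleotide A/C/G/T"
    if row.effect_allele == row.other_allele:
        return f"{row.SNP}: effect_allele equals other_allele"
    if not np.isfinite(row.se) or row.se <= 0:
        return f"{row.SNP}: se must be positive"
    if not np.isfinite(row.beta):
        return f"{row.SNP}: beta must be finite"
    if not (0 < row.pval <= 1):
        return f"{row.SNP}: pval must lie in (0, 1]"
    if not pd.isna(row.eaf) and not (0 < row.eaf < 1):
        return f"{row.SNP}: eaf must lie in (0, 1)"
    if not pd.isna(row.ncase) and not pd.isna(row.ncontrol) and not pd.isna(row.n):
        if int(row.ncase) + int(row.ncontrol) != int(row.n):
            return f"{row.SNP}: ncase + ncontrol != n"
    return None


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    strict: bool = True,
) -> GwasSummary:
    """Read a tab- or comma-separated summary-statistic file.

    ``dialect`` maps canonical column names to the names used in the file
    (e.g. ``{"SNP": "rsid", "pval": "p"}``); it is never guessed silently.
    In strict mode any invalid row raises; otherwise invalid rows are dropped
    with logged reasons.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if dialect:
        rename = {file_col: canon for canon, file_col in dialect.items()}
        df = df.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SummaryFormatError(
                f"{path.name}: mandatory column {col!r} missing "
                f"(available: {list(df.columns)})"
            )
    df["SNP"] = df["SNP"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval", "n", "ncase", "ncontrol"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        else:
            df[col] = np.nan
    df = df.loc[:, list(CANONICAL_COLUMNS)]

    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        msg = _row_problem(row)
        if msg:
            bad_rows.append((i, msg))
    if bad_rows:
        if strict:
            raise ValidationError(f"{path.name}: " + "; ".join(m for _, m in bad_rows[:5]))
        for _, msg in bad_rows:
            logger.warning("%s: dropping row (%s)", path.name, msg)
        df = df.drop(index=[i for i, _ in bad_rows]).reset_index(drop=True)
    label = trait_label if trait_label is not None else path.stem
    return GwasSummary(label, df)


def write_summary_stats(g: GwasSummary, path: str | Path) -> Path:
    """Write ``g`` as a tab-separated file with the canonical header."""
    path = Path(path)
    df = g.records.copy()
    for col in ("n", "ncase", "ncontrol"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df["eaf"] = df["eaf"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    for col in ("beta", "se", "pval"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, sep="\t", index=False)
    return path


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class HarmonizedSet:
    """Exposure–outcome aligned instrument table plus exclusion ledger.

    ``rows`` columns: SNP, beta_x, se_x, beta_y, se_y, eaf_x, eaf_y.
    ``exclusions`` columns: snp_id, reason.
    """

    exposure_label: str
    outcome_label: str
    rows: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        overlap = set(self.rows["SNP"]) & set(self.exclusions["snp_id"])
        if overlap:
            raise ValueError(f"SNPs both retained and excluded: {sorted(overlap)[:5]}")
        if len(self.rows):
            if (self.rows["se_x"] <= 0).any() or (self.rows["se_y"] <= 0).any():
                raise ValueError("harmonized rows must have positive SEs")

    @property
    def n_snp(self) -> int:
        return len(self.rows)

    def exclusion_counts(self) -> dict[str, int]:
        counts = self.exclusions["reason"].value_counts().to_dict()
        for reason in (REASON_MISSING, REASON_PALINDROME, REASON_INCOMPATIBLE):
            counts.setdefault(reason, 0)
        return counts

    def write_exclusions(self, path: str | Path) -> Path:
        path = Path(path)
        self.exclusions.to_csv(path, sep="\t", index=False)
        return path


def _ambiguous(eaf_x: float, eaf_y: float, window: float) -> bool:
    for v in (eaf_x, eaf_y):
        if pd.isna(v) or abs(v - 0.5) <= window:
            return True
    return False


def harmonize(
    exposure: GwasSummary,
    outcome: GwasSummary,
    palindrome_policy: str = "exclude_ambiguous",
    maf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effect alleles with the exposure's instruments.

    For each exposure instrument: absent from the outcome table →
    ``missing_in_outcome``; allele labels matching after an effect/other swap →
    outcome beta negated and eaf complemented; palindromic (A/T or C/G) SNPs →
    excluded under ``exclude_all``, or under ``exclude_ambiguous`` excluded only
    when either trait's eaf lies within ``0.5 ± maf_window`` (or is missing),
    otherwise strand-resolved by frequency agreement; any other allele
    configuration → ``incompatible_alleles``.  Rows plus exclusions always
    partition the instrument set.
    """
    if palindrome_policy not in ("exclude_all", "exclude_ambiguous"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    if len(exposure) == 0:
        raise ValueError("exposure instrument set is empty")
    out_idx = outcome.records.set_index("SNP")

    rows: list[dict] = []
    excl: list[tuple[str, str]] = []
    for rec in exposure.records.itertuples(index=False):
        snp = rec.SNP
        if snp not in out_idx.index:
            excl.append((snp, REASON_MISSING))
            continue
        o = out_idx.loc[snp]
        ea, oa = rec.effect_allele, rec.other_allele
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        if {o_ea, o_oa} != {ea, oa}:
            excl.append((snp, REASON_INCOMPATIBLE))
            continue
        swapped = o_ea != ea
        beta_y = -o["beta"] if swapped else o["beta"]
        eaf_y = o["eaf"]
        if swapped and not pd.isna(eaf_y):
            eaf_y = 1.0 - eaf_y
        if is_palindromic(ea, oa):
            if palindrome_policy == "exclude_all":
                excl.append((snp, REASON_PALINDROME))
                continue
            if _ambiguous(rec.eaf, eaf_y, maf_window):
                excl.append((snp, REASON_PALINDROME))
                continue
            # Strand resolution: allele labels cannot distinguish strands for
            # palindromic pairs, so alignment follows frequency agreement.
            if (rec.eaf - 0.5) * (eaf_y - 0.5) < 0:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
        rows.append(
            {
                "SNP": snp,
                "beta_x": float(rec.beta),
                "se_x": float(rec.se),
                "beta_y": float(beta_y),
                "se_y": float(o["se"]),
                "eaf_x": float(rec.eaf) if not pd.isna(rec.eaf) else np.nan,
                "eaf_y": float(eaf_y) if not pd.isna(eaf_y) else np.nan,
            }
        )

    rows_df = pd.DataFrame(
        rows, columns=["SNP", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"]
    )
    excl_df = pd.DataFrame(excl, columns=["snp_id", "reason"])
    if rows_df.empty:
        raise HarmonizationError(
            f"no harmonizable instruments for {exposure.trait_label!r} -> "
            f"{outcome.trait_label!r} ({len(excl_df)} excluded)"
        )
    assert len(rows_df) + len(excl_df) == len(exposure)
    return HarmonizedSet(exposure.trait_label, outcome.trait_label, rows_df, excl_df)
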