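"""Instrument selection and strength: LD clumping, R² and the F-statistic.

Candidates are SNPs below a genome-wide significance threshold (default
5 × 10⁻⁸); greedy clumping repeatedly keeps the remaining candidate with the
smallest p-value and discards candidates in LD (r² above threshold, default
0.1) with it.  Instrument strength is summarised by the variance explained
R² and the F-statistic, with F > 10 the conventional weak-instrument bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_io import GwasSummary

logger = logging.getLogger("mrkit.instruments")

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.1
WEAK_INSTRUMENT_F = 10.0


class EmptySelectionError(ValueError):
    """No SNP passed the significance threshold."""


@dataclass
class LdMatrix:
    """Pairwise squared-correlation (r²) matrix over a set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 matrix must have unit diagonal")
        if (self.r2 < 0).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def pair_r2(self, a: str, b: str) -> float:
        """r² between two SNPs; pairs absent from the matrix count as 0."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            logger.debug("pair (%s, %s) absent from LD matrix; assuming r2=0", a, b)
            return 0.0
        return float(self.r2[ia, ib])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.r2, columns=self.snp_ids)
        df.insert(0, "snp_id", self.snp_ids)
        df.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t")
        snp_ids = df["snp_id"].astype(str).tolist()
        return cls(snp_ids, df.loc[:, snp_ids].to_numpy(dtype=float))


@dataclass
class InstrumentSet:
    """LD-independent genome-wide-significant instruments for one exposure."""

    snp_ids: list[str]
    source_trait: str
    p_threshold: float
    r2_threshold: float
    total_r2: float = np.nan
    f_statistic: float = np.nan

    @property
    def k(self) -> int:
        return len(self.snp_ids)


def select_instruments(
    g: GwasSummary,
    p_threshold: float = GENOME_WIDE_P,
    ld: LdMatrix | None = None,
    r2_threshold: float = DEFAULT_CLUMP_R2,
) -> InstrumentSet:
    """Greedy p-ordered LD clumping of genome-wide-significant SNPs.

    Returns kept SNPs in retention order (ascending p, ties broken
    lexicographically by SNP id).  ``ld=None`` treats every pair as
    independent, which is logged.
    """
    cand = g.records.loc[g.records["pval"] < p_threshold, ["SNP", "pval"]]
    if cand.empty:
        raise EmptySelectionError(
            f"no SNP in {g.trait_label!r} passes p < {p_threshold:g}"
        )
    if ld is None:
        logger.info("no LD matrix supplied for %s; assuming independence", g.trait_label)
    cand = cand.sort_values(["pval", "SNP"], kind="mergesort")
    kept: list[str] = []
    unseen = set(ld.snp_ids) if ld is not None else set()
    for snp in cand["SNP"]:
        if ld is not None and snp not in unseen:
            logger.warning("SNP %s absent from LD matrix; treated as independent", snp)
        if ld is None or all(ld.pair_r2(snp, k) <= r2_threshold for k in kept):
            kept.append(snp)
    return InstrumentSet(kept, g.trait_label, p_threshold, r2_threshold)


def instrument_r2(
    records: pd.DataFrame, n: float | None = None, method: str = "z_based"
) -> tuple[np.ndarray, float]:
    """Per-SNP and total variance in the exposure explained by the instruments.

    ``frequency``: r²_j = 2 p_j (1−p_j) β_j² (requires eaf; beta in SD units).
    ``z_based``:   r²_j = β_j² / (β_j² + n_j se_j²).
    The total is the sum of the per-SNP terms, capped just below 1 with a
    warning if the sum exceeds it.
    """
    beta = records["beta"].to_numpy(dtype=float)
    if method == "frequency":
        eaf = records["eaf"].to_numpy(dtype=float)
        if np.isnan(eaf).any():
            raise ValueError(
                "frequency method requires eaf for every SNP; use method='z_based'"
            )
        r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    elif method == "z_based":
        se = records["se"].to_numpy(dtype=float)
        if n is None:
            n_arr = records["n"].to_numpy(dtype=float)
            if np.isnan(n_arr).any():
                raise ValueError("z_based method requires sample size n")
        else:
            n_arr = np.full_like(beta, float(n))
        r2 = beta**2 / (beta**2 + n_arr * se**2)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = float(r2.sum())
    if total >= 1.0:
        logger.warning("total R^2 %.3f >= 1; capping below 1", total)
        total = 1.0 - 1e-12
    return r2, total


def f_statistic(total_r2: float, n: float, k: int) -> float:
    """F = (R²/k) / ((1−R²)/(n−k−1)); strength of the instrument set."""
    if not (0 <= total_r2 < 1):
        raise ValueError("total_r2 must lie in [0, 1)")
    if n <= k + 1 or k < 1:
        raise ValueError("requires n > k + 1 >= 2")
    return (total_r2 / k) / ((1.0 - total_r2) / (n - k - 1))


def per_snp_f(records: pd.DataFrame) -> np.ndarray:
    """Per-SNP F_j = (β_j / se_j)²."""
    beta = records["beta"].to_numpy(dtype=float)
    se = records["se"].to_numpy(dtype=float)
    return (beta / se) ** 2
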