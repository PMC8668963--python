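"""Heterogeneity and sensitivity diagnostics.

Cochran's Q (IVW form, J−1 df) and Rücker's Q (Egger residuals, J−2 df)
test whether the per-SNP Wald ratios are mutually consistent; leave-one-out
re-estimates the IVW slope omitting each SNP in turn; funnel/forest/scatter
tables are emitted plot-ready rather than drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    InsufficientInstrumentsError,
    MrEstimate,
    PleiotropyResult,
    RatioEstimates,
    _arrays,
    _egger_orient,
    mr_ivw,
    ratio_estimates,
)
from .summary_io import HarmonizedSet

logger = logging.getLogger("mrkit.diagnostics")


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float
    method: str = "ivw"


@dataclass
class LeaveOneOutSeries:
    """IVW slope re-estimated J times, omitting each SNP once."""

    entries: pd.DataFrame  # snp_id, b, se, pval, sign_flip, crosses_threshold
    full: MrEstimate

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def flagged(self) -> pd.DataFrame:
        return self.entries[self.entries["sign_flip"] | self.entries["crosses_threshold"]]


def cochran_q(r: RatioEstimates, b: float) -> HeterogeneityResult:
    """Q = Σ σ_j⁻² (θ_j − b)², df = J−1, p from the chi-square upper tail."""
    J = len(r)
    if J < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    q = float(np.sum(r.sigma**-2 * (r.theta - b) ** 2))
    df = J - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)), "ivw")


def rucker_q(
    h: HarmonizedSet, pleio: PleiotropyResult, egger: MrEstimate
) -> HeterogeneityResult:
    """Rücker's Q: weighted residual SS about the fitted Egger line, df = J−2.

    Uses the same β_X ≥ 0 orientation as the Egger fit.
    """
    bx, _, by, sy = _arrays(h)
    J = len(bx)
    if J < 3:
        raise InsufficientInstrumentsError("Rucker's Q requires >= 3 instruments")
    bx, by = _egger_orient(bx, by)
    resid = by - pleio.intercept - egger.b * bx
    q = float(np.sum(sy**-2 * resid**2))
    df = J - 2
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)), "egger")


def leave_one_out(
    h: HarmonizedSet, significance: float = 0.05, re_mode: str = "multiplicative_floor"
) -> LeaveOneOutSeries:
    """IVW omitting each SNP once; flags sign flips and significance crossings."""
    J = h.n_snp
    if J < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full = mr_ivw(h, re_mode=re_mode)
    full_sig = full.pval < significance
    records = []
    for i in range(J):
        sub = HarmonizedSet(
            h.exposure_label,
            h.outcome_label,
            h.rows.drop(index=h.rows.index[i]).reset_index(drop=True),
            h.exclusions,
        )
        est = mr_ivw(sub, re_mode=re_mode)
        records.append(
            {
                "snp_id": h.rows["SNP"].iloc[i],
                "b": est.b,
                "se": est.se,
                "pval": est.pval,
                "sign_flip": bool(np.sign(est.b) != np.sign(full.b) and full.b != 0),
                "crosses_threshold": bool((est.pval < significance) != full_sig),
            }
        )
    return LeaveOneOutSeries(pd.DataFrame(records), full)


def funnel_data(r: RatioEstimates, b: float) -> tuple[pd.DataFrame, float]:
    """Funnel table (θ_j, precision 1/σ_j) with an asymmetry score.

    The score is the Spearman rank correlation between θ_j − b and σ_j:
    near 0 for a symmetric funnel, signed when imprecise instruments drift
    systematically to one side.  Undefined (NaN) for fewer than 3 SNPs.
    """
    table = pd.DataFrame(
        {"snp_id": r.snp_ids, "theta": r.theta, "precision": 1.0 / r.sigma}
    )
    if len(r) < 3:
        return table, float("nan")
    score = stats.spearmanr(r.theta - b, r.sigma).statistic
    return table, float(score)


def scatter_data(
    h: HarmonizedSet,
    estimates: list[MrEstimate],
    pleio: PleiotropyResult | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP effect scatter plus per-method fitted lines (plot-ready)."""
    points = h.rows[["SNP", "beta_x", "se_x", "beta_y", "se_y"]].copy()
    lines = pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "intercept": [
                pleio.intercept if (e.method == "egger" and pleio is not None) else 0.0
                for e in estimates
            ],
            "slope": [e.b for e in estimates],
        }
    )
    return points, lines


def forest_data(h: HarmonizedSet, full: MrEstimate) -> pd.DataFrame:
    """Per-SNP Wald ratios with 95% CIs plus the pooled estimate (plot-ready)."""
    r = ratio_estimates(h)
    z = float(stats.norm.ppf(0.975))
    df = pd.DataFrame(
        {
            "snp_id": r.snp_ids,
            "b": r.theta,
            "ci_low": r.theta - z * r.sigma,
            "ci_high": r.theta + z * r.sigma,
        }
    )
    pooled = pd.DataFrame(
        {
            "snp_id": [f"All ({full.method})"],
            "b": [full.b],
            "ci_low": [full.ci_low],
            "ci_high": [full.ci_high],
        }
    )
    return pd.concat([df, pooled], ignore_index=True)
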