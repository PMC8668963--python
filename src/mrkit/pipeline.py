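"""Orchestration: the bidirectional analysis grid.

One :class:`AnalysisSpec` describes a single exposure→outcome MR analysis
(instrument selection → harmonization → estimators → diagnostics → power);
:func:`run_grid` runs a list of them — e.g. 6 traits × 2 directions = 12
analyses — applies Bonferroni multiplicity control across the grid and
renders report tables: an instrument-strength/power table and per-direction
estimate tables, plus per-analysis diagnostic TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (
    HeterogeneityResult,
    LeaveOneOutSeries,
    cochran_q,
    forest_data,
    funnel_data,
    leave_one_out,
    rucker_q,
    scatter_data,
)
from .estimators import (
    METHOD_NAMES,
    MrEstimate,
    PleiotropyResult,
    mr_egger,
    ratio_estimates,
    run_method,
    to_odds_scale,
)
from .instruments import (
    DEFAULT_CLUMP_R2,
    GENOME_WIDE_P,
    WEAK_INSTRUMENT_F,
    InstrumentSet,
    LdMatrix,
    f_statistic,
    instrument_r2,
    select_instruments,
)
from .power import PowerResult, mr_power
from .summary_io import GwasSummary, HarmonizedSet, harmonize, read_summary_stats

logger = logging.getLogger("mrkit.pipeline")

DEFAULT_ALPHA = 0.05
#: OR against which post-hoc power is evaluated by default.
DEFAULT_POWER_OR = 1.2


@dataclass
class AnalysisSpec:
    """Configuration for one exposure→outcome analysis."""

    exposure: str | Path | GwasSummary
    outcome: str | Path | GwasSummary
    direction_label: str = "forward"
    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = DEFAULT_CLUMP_R2
    palindrome_policy: str = "exclude_ambiguous"
    maf_window: float = 0.08
    methods: tuple[str, ...] = METHOD_NAMES
    n_boot: int = 1000
    seed: int | None = None
    ld: str | Path | LdMatrix | None = None
    power_or: float = DEFAULT_POWER_OR
    exposure_dialect: Mapping[str, str] | None = None
    outcome_dialect: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must lie in [0, 1]")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class AnalysisResult:
    """Everything one analysis produced (or its failure)."""

    exposure_label: str
    outcome_label: str
    direction_label: str
    failed: bool = False
    error: str = ""
    accounting: dict[str, int] = field(default_factory=dict)
    instruments: InstrumentSet | None = None
    harmonized: HarmonizedSet | None = None
    total_r2: float = np.nan
    f_stat: float = np.nan
    weak_instruments: bool = False
    power: PowerResult | None = None
    estimates: dict[str, MrEstimate] = field(default_factory=dict)
    pleiotropy: PleiotropyResult | None = None
    heterogeneity: list[HeterogeneityResult] = field(default_factory=list)
    loo: LeaveOneOutSeries | None = None
    funnel: pd.DataFrame | None = None
    funnel_symmetry: float = np.nan
    scatter_points: pd.DataFrame | None = None
    scatter_lines: pd.DataFrame | None = None
    forest: pd.DataFrame | None = None


@dataclass
class GridReport:
    """Results of the full analysis grid with multiplicity control."""

    analyses: list[AnalysisResult]
    alpha: float
    bonferroni: float

    @property
    def m(self) -> int:
        return len(self.analyses)

    def significance_calls(self, primary: str = "ivw") -> dict[str, bool]:
        calls = {}
        for a in self.analyses:
            key = f"{a.exposure_label}->{a.outcome_label}"
            est = a.estimates.get(primary)
            calls[key] = bool(est is not None and est.pval < self.bonferroni)
        return calls


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _load_summary(
    src: str | Path | GwasSummary, dialect: Mapping[str, str] | None
) -> GwasSummary:
    if isinstance(src, GwasSummary):
        return src
    return read_summary_stats(src, dialect=dialect)


def _load_ld(src: str | Path | LdMatrix | None) -> LdMatrix | None:
    if src is None or isinstance(src, LdMatrix):
        return src
    return LdMatrix.from_tsv(src)


def run_analysis(spec: AnalysisSpec) -> AnalysisResult:
    """Run one full analysis; stage failures are wrapped with the stage name."""
    stage = "load"
    try:
        exposure = _load_summary(spec.exposure, spec.exposure_dialect)
        outcome = _load_summary(spec.outcome, spec.outcome_dialect)
        ld = _load_ld(spec.ld)

        stage = "select_instruments"
        inst = select_instruments(exposure, spec.p_threshold, ld, spec.clump_r2)
        exp_inst = exposure.subset(inst.snp_ids)

        stage = "harmonize"
        h = harmonize(
            exp_inst, outcome, spec.palindrome_policy, maf_window=spec.maf_window
        )
        counts = h.exclusion_counts()
        accounting = {
            "initial": inst.k,
            "missing_in_outcome": counts["missing_in_outcome"],
            "palindromic": counts["palindromic_ambiguous"],
            "incompatible": counts["incompatible_alleles"],
            "final": h.n_snp,
        }

        stage = "instrument_strength"
        retained = exp_inst.subset(h.rows["SNP"].tolist())
        _, total_r2 = instrument_r2(retained.records, method="z_based")
        n_exp = float(np.nanmedian(retained.records["n"]))
        f_stat = np.nan
        if np.isfinite(n_exp):
            f_stat = f_statistic(total_r2, n_exp, h.n_snp)
        inst.total_r2, inst.f_statistic = total_r2, f_stat
        weak = bool(np.isfinite(f_stat) and f_stat <= WEAK_INSTRUMENT_F)
        if weak:
            logger.warning(
                "%s -> %s: F = %.2f <= 10, weak instruments",
                exposure.trait_label, outcome.trait_label, f_stat,
            )

        stage = "estimators"
        estimates: dict[str, MrEstimate] = {}
        pleio = None
        for method in spec.methods:
            if method == "egger":
                est, pleio = mr_egger(h)
            else:
                est = run_method(h, method, n_boot=spec.n_boot, seed=spec.seed)
            estimates[method] = to_odds_scale(est)

        stage = "diagnostics"
        het: list[HeterogeneityResult] = []
        r = ratio_estimates(h)
        if "ivw" in estimates:
            het.append(cochran_q(r, estimates["ivw"].b))
        if "egger" in estimates and pleio is not None:
            het.append(rucker_q(h, pleio, estimates["egger"]))
        loo = leave_one_out(h) if h.n_snp >= 3 else None
        ref_b = estimates.get("ivw", next(iter(estimates.values()))).b
        funnel, symmetry = funnel_data(r, ref_b)
        points, lines = scatter_data(h, list(estimates.values()), pleio)
        forest = forest_data(h, estimates["ivw"]) if "ivw" in estimates else None

        stage = "power"
        power = None
        out_records = outcome.records
        has_cases = out_records["ncase"].notna().any()
        n_out = float(np.nanmedian(out_records["n"]))
        if np.isfinite(n_out) and 0 < total_r2 < 1:
            if has_cases:
                k_frac = float(
                    np.nanmedian(out_records["ncase"] / out_records["n"])
                )
                power = mr_power(
                    n_out, total_r2, np.log(spec.power_or),
                    outcome_type="binary", case_fraction=k_frac,
                )
            else:
                power = mr_power(
                    n_out, total_r2, np.log(spec.power_or), outcome_type="continuous"
                )

        return AnalysisResult(
            exposure_label=exposure.trait_label,
            outcome_label=outcome.trait_label,
            direction_label=spec.direction_label,
            accounting=accounting,
            instruments=inst,
            harmonized=h,
            total_r2=total_r2,
            f_stat=f_stat,
            weak_instruments=weak,
            power=power,
            estimates=estimates,
            pleiotropy=pleio,
            heterogeneity=het,
            loo=loo,
            funnel=funnel,
            funnel_symmetry=symmetry,
            scatter_points=points,
            scatter_lines=lines,
            forest=forest,
        )
    except Exception as exc:  # a failed analysis degrades to a failure row
        exp_label = (
            spec.exposure.trait_label
            if isinstance(spec.exposure, GwasSummary)
            else Path(str(spec.exposure)).stem
        )
        out_label = (
            spec.outcome.trait_label
            if isinstance(spec.outcome, GwasSummary)
            else Path(str(spec.outcome)).stem
        )
        logger.error("analysis %s -> %s failed at %s: %s", exp_label, out_label, stage, exc)
        return AnalysisResult(
            exposure_label=exp_label,
            outcome_label=out_label,
            direction_label=spec.direction_label,
            failed=True,
            error=f"{stage}: {exc}",
        )


def run_grid(
    specs: Sequence[AnalysisSpec],
    alpha: float = DEFAULT_ALPHA,
    out_dir: str | Path | None = None,
) -> GridReport:
    """Run every analysis, apply Bonferroni control, optionally write reports."""
    if not specs:
        raise ValueError("specs must be nonempty")
    results = [run_analysis(s) for s in specs]
    report = GridReport(results, alpha, bonferroni_threshold(alpha, len(specs)))
    if out_dir is not None:
        write_grid_reports(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# Report rendering: OR/CI at 3 decimals, p in scientific notation below 1e-3,
# thresholds rendered at 3 decimals but carried at full precision internally.

def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return f"{p:.2e}" if p < 1e-3 else f"{p:.3f}"


def _fmt_or_ci(e: MrEstimate) -> str:
    return f"{e.odds_ratio:.3f} ({e.or_ci_low:.3f}-{e.or_ci_high:.3f})"


def strength_table(report: GridReport) -> pd.DataFrame:
    """Instrument strength and power per analysis (R², F, power)."""
    rows = []
    for a in report.analyses:
        rows.append(
            {
                "exposure": a.exposure_label,
                "outcome": a.outcome_label,
                "direction": a.direction_label,
                "n_snp": a.accounting.get("final", 0),
                "r2_pct": "" if not np.isfinite(a.total_r2) else f"{100 * a.total_r2:.2f}%",
                "f_statistic": "" if not np.isfinite(a.f_stat) else f"{a.f_stat:.2f}",
                "power_pct": "" if a.power is None else f"{100 * a.power.power:.1f}%",
                "status": "failed" if a.failed else "ok",
            }
        )
    return pd.DataFrame(rows)


def estimates_table(report: GridReport, direction: str | None = None) -> pd.DataFrame:
    """Per-method causal estimates, OR (95% CI), heterogeneity and Egger intercept."""
    rows = []
    for a in report.analyses:
        if direction is not None and a.direction_label != direction:
            continue
        if a.failed:
            rows.append(
                {
                    "exposure": a.exposure_label,
                    "outcome": a.outcome_label,
                    "n_snp": 0,
                    "method": "",
                    "or_95ci": "",
                    "pval": "",
                    "q": "",
                    "q_pval": "",
                    "egger_intercept": "",
                    "p_egger_intercept": "",
                    "status": f"failed ({a.error})",
                }
            )
            continue
        q_by_method = {hr.method: hr for hr in a.heterogeneity}
        for method, est in a.estimates.items():
            hr = q_by_method.get(method)
            rows.append(
                {
                    "exposure": a.exposure_label,
                    "outcome": a.outcome_label,
                    "n_snp": est.n_snp,
                    "method": method,
                    "or_95ci": _fmt_or_ci(est),
                    "pval": _fmt_p(est.pval),
                    "q": f"{hr.q:.2f}" if hr else "",
                    "q_pval": _fmt_p(hr.pval) if hr else "",
                    "egger_intercept": (
                        f"{a.pleiotropy.intercept:.3f}"
                        if method == "egger" and a.pleiotropy
                        else ""
                    ),
                    "p_egger_intercept": (
                        _fmt_p(a.pleiotropy.intercept_p)
                        if method == "egger" and a.pleiotropy
                        else ""
                    ),
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)


def write_grid_reports(report: GridReport, out_dir: str | Path) -> list[Path]:
    """Write table1 (strength/power), per-direction estimate tables and
    per-analysis diagnostics; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "table1.tsv"
    strength_table(report).to_csv(p, sep="\t", index=False)
    written.append(p)

    directions = list(dict.fromkeys(a.direction_label for a in report.analyses))
    for i, d in enumerate(directions):
        name = f"table{i + 2}.tsv" if len(directions) == 2 else f"estimates_{d}.tsv"
        p = out_dir / name
        estimates_table(report, d).to_csv(p, sep="\t", index=False)
        written.append(p)

    for a in report.analyses:
        if a.failed:
            continue
        tag = f"{a.exposure_label}__{a.outcome_label}"
        het = pd.DataFrame(
            [
                {"method": hr.method, "q": f"{hr.q:.6g}", "df": hr.df, "pval": f"{hr.pval:.6g}"}
                for hr in a.heterogeneity
            ]
        )
        for name, df in (
            ("heterogeneity", het),
            ("loo", a.loo.entries if a.loo is not None else None),
            ("funnel", a.funnel),
            ("scatter", a.scatter_points),
            ("scatter_lines", a.scatter_lines),
            ("forest", a.forest),
            ("exclusions", a.harmonized.exclusions if a.harmonized else None),
        ):
            if df is None:
                continue
            p = out_dir / f"{tag}.{name}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.10g")
            written.append(p)

    log = out_dir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write(f"mrkit {__version__}\n")
        fh.write(f"analyses: {report.m}\n")
        fh.write(f"alpha: {report.alpha}\n")
        fh.write(f"bonferroni_threshold: {report.bonferroni:.6g} (renders {report.bonferroni:.3f})\n")
        for a in report.analyses:
            fh.write(
                f"{a.exposure_label} -> {a.outcome_label} "
                f"[{a.direction_label}] "
                + ("FAILED: " + a.error if a.failed else f"n_snp={a.accounting.get('final')}")
                + "\n"
            )
    written.append(log)
    return written


def load_grid_config(path: str | Path) -> tuple[list[AnalysisSpec], float]:
    """Read a YAML grid configuration: top-level ``alpha`` and ``analyses`` list."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    alpha = float(cfg.get("alpha", DEFAULT_ALPHA))
    base = Path(path).parent
    specs = []
    for entry in cfg["analyses"]:
        specs.append(
            AnalysisSpec(
                exposure=base / entry["exposure"],
                outcome=base / entry["outcome"],
                direction_label=entry.get("direction", "forward"),
                p_threshold=float(entry.get("p_threshold", GENOME_WIDE_P)),
                clump_r2=float(entry.get("clump_r2", DEFAULT_CLUMP_R2)),
                palindrome_policy=entry.get("palindrome_policy", "exclude_ambiguous"),
                maf_window=float(entry.get("maf_window", 0.08)),
                methods=tuple(entry.get("methods", METHOD_NAMES)),
                n_boot=int(entry.get("n_boot", 1000)),
                seed=entry.get("seed"),
                ld=(base / entry["ld"]) if "ld" in entry else None,
                power_or=float(entry.get("power_or", DEFAULT_POWER_OR)),
            )
        )
    return specs, alpha
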