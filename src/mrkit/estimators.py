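"""The five two-sample MR causal estimators.

Given a harmonized instrument table with per-SNP exposure effects β_Xj (SE
se_Xj) and outcome effects β_Yj (SE se_Yj), each estimator combines the
per-SNP Wald ratios θ_j = β_Yj/β_Xj into a single causal slope:

* ``mr_ivw`` — inverse-variance weighted regression of β_Y on β_X through
  the origin, the primary method, with a multiplicative random-effects
  overdispersion floored at 1;
* ``mr_egger`` — weighted regression with a free intercept; the intercept
  is a test for directional horizontal pleiotropy, the slope is consistent
  under the InSIDE assumption;
* ``mr_weighted_median`` — consistent when instruments carrying at least
  half the weight are valid; SE by parametric bootstrap;
* ``mr_mode`` — kernel-density mode of the Wald ratios (simple or
  inverse-variance weighted), consistent when the largest homogeneous
  subset of instruments is valid.

Slopes are on the log-odds (binary outcome) or SD (continuous outcome)
scale; :func:`to_odds_scale` exponentiates slope and CI into an OR.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_io import HarmonizedSet

logger = logging.getLogger("mrkit.estimators")

Z975 = float(stats.norm.ppf(0.975))

DEFAULT_N_BOOT = 1000
DEFAULT_PHI = 1.0
DEFAULT_GRID_SIZE = 512


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios θ_j = β_Yj/β_Xj and first-order SEs σ_j = se_Yj/|β_Xj|."""

    snp_ids: list[str]
    theta: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if (self.sigma <= 0).any():
            raise ValueError("ratio SEs must be positive")

    def __len__(self) -> int:
        return len(self.theta)


@dataclass
class MrEstimate:
    """One method's causal estimate on the slope scale, plus the OR transform."""

    method: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    #: for continuous outcomes the "OR" is exp(slope) per SD of exposure
    scale_note: str = ""


@dataclass
class PleiotropyResult:
    """MR-Egger intercept test for directional horizontal pleiotropy."""

    intercept: float
    intercept_se: float
    intercept_p: float


def _arrays(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    r = h.rows
    return (
        r["beta_x"].to_numpy(dtype=float),
        r["se_x"].to_numpy(dtype=float),
        r["beta_y"].to_numpy(dtype=float),
        r["se_y"].to_numpy(dtype=float),
    )


def ratio_estimates(h: HarmonizedSet) -> RatioEstimates:
    """Per-SNP Wald ratios with first-order (outcome-only) standard errors."""
    bx, _, by, sy = _arrays(h)
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise ValueError(
            f"zero exposure beta for SNP {h.rows['SNP'].iloc[zero[0]]!r}"
        )
    return RatioEstimates(h.rows["SNP"].tolist(), by / bx, sy / np.abs(bx))


def _package(method: str, b: float, se: float, p: float, n_snp: int,
             crit: float = Z975) -> MrEstimate:
    return MrEstimate(
        method=method,
        b=float(b),
        se=float(se),
        ci_low=float(b - crit * se),
        ci_high=float(b + crit * se),
        pval=float(max(p, np.nextafter(0, 1))),
        n_snp=n_snp,
    )


def mr_ivw(h: HarmonizedSet, re_mode: str = "multiplicative_floor") -> MrEstimate:
    """Random-effects IVW: weighted regression of β_Y on β_X through the origin.

    Weights are se_Yj⁻².  Under ``multiplicative_floor`` the fixed-effect SE
    is inflated by √(Q/(J−1)) when Cochran's Q exceeds its degrees of freedom
    (underdispersion is not credited); ``fixed`` reports the fixed-effect SE.
    """
    if re_mode not in ("multiplicative_floor", "fixed"):
        raise ValueError(f"unknown re_mode {re_mode!r}")
    bx, _, by, sy = _arrays(h)
    J = len(bx)
    if J < 2:
        raise InsufficientInstrumentsError(f"IVW requires >= 2 instruments, got {J}")
    w = sy**-2
    sxx = float(np.sum(w * bx * bx))
    b = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - b * bx) ** 2))
    se = se_fixed
    if re_mode == "multiplicative_floor":
        se = se_fixed * max(1.0, np.sqrt(q / (J - 1)))
    p = 2.0 * stats.norm.sf(abs(b) / se)
    return _package("ivw", b, se, p, J)


def _egger_orient(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def mr_egger(h: HarmonizedSet) -> tuple[MrEstimate, PleiotropyResult]:
    """MR-Egger weighted regression β_Y = α + b·β_X with weights se_Y⁻².

    Rows are oriented so every β_X ≥ 0.  SEs are inflated by
    max(1, √(Q_E/(J−2))) where Q_E is the weighted residual sum of squares;
    p-values use t with J−2 degrees of freedom.
    """
    bx, _, by, sy = _arrays(h)
    J = len(bx)
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {J}")
    bx, by = _egger_orient(bx, by)
    w = sy**-2
    # Weighted normal equations for [alpha, b]
    s0, s1, s2 = np.sum(w), np.sum(w * bx), np.sum(w * bx * bx)
    t0, t1 = np.sum(w * by), np.sum(w * bx * by)
    det = s0 * s2 - s1 * s1
    alpha = (s2 * t0 - s1 * t1) / det
    b = (s0 * t1 - s1 * t0) / det
    resid = by - alpha - b * bx
    q_e = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q_e / (J - 2)))
    var_alpha = s2 / det
    var_b = s0 / det
    se_alpha = scale * np.sqrt(var_alpha)
    se_b = scale * np.sqrt(var_b)
    df = J - 2
    p_b = 2.0 * stats.t.sf(abs(b) / se_b, df)
    p_alpha = 2.0 * stats.t.sf(abs(alpha) / se_alpha, df)
    crit = float(stats.t.ppf(0.975, df))
    est = _package("egger", b, se_b, p_b, J, crit=crit)
    pleio = PleiotropyResult(float(alpha), float(se_alpha), float(max(p_alpha, 1e-300)))
    return est, pleio


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    t = theta[order]
    ww = w[order] / w.sum()
    s = np.cumsum(ww)
    p = s - ww / 2.0
    # np.interp clamps to the extreme theta outside [p_1, p_J]
    return float(np.interp(0.5, p, t))


def _bootstrap_ratios(
    h: HarmonizedSet, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric bootstrap draws of (theta*, sigma*), shape (n_boot, J)."""
    bx, sx, by, sy = _arrays(h)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_star = rng.normal(by, sy, size=(n_boot, len(bx)))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    return by_star / bx_star, sy / np.abs(bx_star)


def mr_weighted_median(
    h: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None
) -> MrEstimate:
    """Weighted median of the Wald ratios; SE by parametric bootstrap.

    The estimate interpolates the ordered θ_(j) against cumulative weight
    midpoints p_j = S_j − w'_j/2 at 0.5.  The bootstrap redraws β_X and β_Y
    from normal distributions centred on the observed values.
    """
    r = ratio_estimates(h)
    J = len(r)
    if J < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {J}"
        )
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    b = _weighted_median(r.theta, r.sigma**-2)
    rng = np.random.default_rng(seed)
    theta_star, sigma_star = _bootstrap_ratios(h, n_boot, rng)
    reps = _weighted_median_batch(theta_star, sigma_star**-2)
    se = float(np.std(reps, ddof=1))
    p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else 1.0
    return _package("weighted_median", b, se, p, J)


def _weighted_median_batch(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median over a (B, J) batch (same interpolation rule)."""
    B, J = theta.shape
    order = np.argsort(theta, axis=1, kind="mergesort")
    t = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    ww = ww / ww.sum(axis=1, keepdims=True)
    p = np.cumsum(ww, axis=1) - ww / 2.0
    idx = (p < 0.5).sum(axis=1)
    rows = np.arange(B)
    lo = np.clip(idx - 1, 0, J - 1)
    hi = np.clip(idx, 0, J - 1)
    p_lo, p_hi = p[rows, lo], p[rows, hi]
    t_lo, t_hi = t[rows, lo], t[rows, hi]
    span = np.where(p_hi > p_lo, p_hi - p_lo, 1.0)
    est = t_lo + (0.5 - p_lo) / span * (t_hi - t_lo)
    est = np.where(idx == 0, t[:, 0], est)   # clamp at the boundaries
    est = np.where(idx == J, t[:, -1], est)
    return est


def _mode_bandwidth(theta: np.ndarray, phi: float) -> float:
    J = len(theta)
    sd = float(np.std(theta, ddof=1)) if J > 1 else 0.0
    mad = float(np.median(np.abs(theta - np.median(theta)))) * 1.4826
    candidates = [c for c in (sd, mad) if c > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * J ** (-1.0 / 5.0)


def _mode_point(theta: np.ndarray, u: np.ndarray, phi: float, grid_size: int) -> float:
    h = _mode_bandwidth(theta, phi)
    if h == 0.0:
        return float(np.median(theta))
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_size)
    # The data points are appended to the evaluation grid so a dense cluster
    # can never fall between grid points when outliers stretch the range.
    grid = np.concatenate([grid, theta])
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ u
    return float(grid[np.argmax(dens)])


def _mode_batch(
    theta: np.ndarray, u: np.ndarray, phi: float, grid_size: int
) -> np.ndarray:
    """Vectorised KDE-mode over a (B, J) batch of bootstrap replicates."""
    B, J = theta.shape
    sd = theta.std(axis=1, ddof=1)
    med = np.median(theta, axis=1, keepdims=True)
    mad = np.median(np.abs(theta - med), axis=1) * 1.4826
    both = np.stack([sd, mad])
    both = np.where(both > 0, both, np.inf)
    s = np.min(both, axis=0)
    h = phi * 0.9 * s * J ** (-1.0 / 5.0)
    degenerate = ~np.isfinite(h) | (h <= 0)
    h = np.where(degenerate, 1.0, h)
    lo = theta.min(axis=1) - 3 * h
    hi = theta.max(axis=1) + 3 * h
    frac = np.linspace(0.0, 1.0, grid_size)
    out = np.empty(B)
    # Kernel evaluation in float32 (the argmax over a 512-point grid is
    # insensitive to it); batched matmul for the weighted sum over SNPs.
    theta32 = theta.astype(np.float32)
    u32 = u.astype(np.float32)[:, :, None]
    chunk = max(1, int(4e6 // (grid_size * J)))  # bound peak memory
    for start in range(0, B, chunk):
        sl = slice(start, min(start + chunk, B))
        grid = lo[sl, None] + frac[None, :] * (hi - lo)[sl, None]
        # data points appended so clusters cannot vanish between grid points
        grid = np.concatenate([grid, theta[sl]], axis=1)
        d = grid.astype(np.float32)[:, :, None] - theta32[sl, None, :]
        np.multiply(d, d, out=d)
        d *= (-0.5 / h[sl] ** 2).astype(np.float32)[:, None, None]
        np.exp(d, out=d)
        dens = (d @ u32[sl])[:, :, 0]
        out[sl] = np.take_along_axis(
            grid, np.argmax(dens, axis=1)[:, None], axis=1
        )[:, 0]
    out = np.where(degenerate, np.median(theta, axis=1), out)
    return out


def mr_mode(
    h: HarmonizedSet,
    weighted: bool = True,
    phi: float = DEFAULT_PHI,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> MrEstimate:
    """Mode-based estimate: argmax of a normal-kernel density over the ratios.

    Bandwidth h = phi · 0.9 · min(sd, 1.4826·MAD) · J^(−1/5); weights u_j are
    uniform (simple mode) or normalised inverse-variance (weighted mode).
    When every θ_j coincides the bandwidth degenerates and the common value is
    returned with a logged note.  SE by the same parametric bootstrap as the
    weighted median.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    r = ratio_estimates(h)
    J = len(r)
    if J < 3:
        raise InsufficientInstrumentsError(f"mode requires >= 3 instruments, got {J}")
    if np.ptp(r.theta) == 0.0:
        logger.info("degenerate bandwidth: all Wald ratios identical")
    w = r.sigma**-2
    u = (w / w.sum()) if weighted else np.full(J, 1.0 / J)
    b = _mode_point(r.theta, u, phi, grid_size)
    rng = np.random.default_rng(seed)
    theta_star, sigma_star = _bootstrap_ratios(h, n_boot, rng)
    if weighted:
        w_star = sigma_star**-2
        u_star = w_star / w_star.sum(axis=1, keepdims=True)
    else:
        u_star = np.full_like(theta_star, 1.0 / J)
    reps = _mode_batch(theta_star, u_star, phi, grid_size)
    se = float(np.std(reps, ddof=1))
    p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else 1.0
    return _package("weighted_mode" if weighted else "simple_mode", b, se, p, J)


def to_odds_scale(e: MrEstimate) -> MrEstimate:
    """Populate OR fields: OR = exp(b), CI = exp(ci_low), exp(ci_high)."""
    return dataclasses.replace(
        e,
        odds_ratio=float(np.exp(e.b)),
        or_ci_low=float(np.exp(e.ci_low)),
        or_ci_high=float(np.exp(e.ci_high)),
    )


#: Names accepted by :func:`run_method` and the pipeline's ``methods`` lists.
METHOD_NAMES = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


def run_method(
    h: HarmonizedSet,
    method: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MrEstimate:
    """Dispatch a single estimator by name (Egger's intercept is dropped here)."""
    if method == "ivw":
        return mr_ivw(h)
    if method == "egger":
        return mr_egger(h)[0]
    if method == "weighted_median":
        return mr_weighted_median(h, n_boot=n_boot, seed=seed)
    if method == "simple_mode":
        return mr_mode(h, weighted=False, n_boot=n_boot, seed=seed)
    if method == "weighted_mode":
        return mr_mode(h, weighted=True, n_boot=n_boot, seed=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {METHOD_NAMES}")
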