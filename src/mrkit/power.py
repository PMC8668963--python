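"""Post-hoc power for two-sample MR under the asymptotic normal approximation.

The non-centrality of the IVW z-statistic grows with the outcome sample
size n, the variance in the exposure explained by the instruments (R²) and
the alternative effect.  For a binary outcome with case fraction K the
effective sample size is scaled by K(1−K):

    continuous:  power = Φ(|b|·√(n·R²) − z_{1−α/2})
    binary:      power = Φ(|log OR|·√(n·R²·K(1−K)) − z_{1−α/2})

This is the one-tailed form of the two-sided test at level α (the far tail
is negligible except under the null, where power → α/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PowerResult:
    power: float
    alpha: float
    n_outcome: float
    r2_exposure: float
    effect_alt: float
    outcome_type: str
    case_fraction: float | None = None


def mr_power(
    n: float,
    r2: float,
    effect_alt: float,
    alpha: float = 0.05,
    outcome_type: str = "binary",
    case_fraction: float | None = None,
) -> PowerResult:
    """Asymptotic power to detect ``effect_alt`` (log-OR or SD-unit slope).

    ``n`` is the outcome sample size, ``r2`` the instrument R² on the
    exposure.  Binary outcomes require ``case_fraction`` in (0, 1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 < r2 < 1):
        raise ValueError("r2 must lie in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if outcome_type == "binary":
        if case_fraction is None or not (0 < case_fraction < 1):
            raise ValueError("binary outcome requires case_fraction in (0, 1)")
        ncp = abs(effect_alt) * np.sqrt(n * r2 * case_fraction * (1.0 - case_fraction))
    elif outcome_type == "continuous":
        ncp = abs(effect_alt) * np.sqrt(n * r2)
    else:
        raise ValueError(f"unknown outcome_type {outcome_type!r}")
    power = float(stats.norm.cdf(ncp - z))
    return PowerResult(
        power=power,
        alpha=alpha,
        n_outcome=float(n),
        r2_exposure=float(r2),
        effect_alt=float(effect_alt),
        outcome_type=outcome_type,
        case_fraction=case_fraction,
    )
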