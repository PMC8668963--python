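import numpy as np
import pandas as pd
import pytest

from mrkit import GwasSummary, HarmonizedSet


def make_summary(
    label: str,
    snps,
    betas,
    ses,
    pvals=None,
    effect_alleles=None,
    other_alleles=None,
    eafs=None,
    n=100_000,
):
    """Build a small GwasSummary from parallel lists."""
    J = len(snps)
    betas = list(betas)
    ses = list(ses)
    if pvals is None:
        from scipy import stats

        pvals = [
            float(np.clip(2 * stats.norm.sf(abs(b) / s), 1e-300, 1.0))
            for b, s in zip(betas, ses)
        ]
    if effect_alleles is None:
        effect_alleles = ["A"] * J
    if other_alleles is None:
        other_alleles = ["G"] * J
    df = pd.DataFrame(
        {
            "SNP": snps,
            "effect_allele": effect_alleles,
            "other_allele": other_alleles,
            "eaf": eafs if eafs is not None else [0.3] * J,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "n": [float(n)] * J,
        }
    )
    return GwasSummary(label, df)


def make_harmonized(beta_x, se_x, beta_y, se_y, snps=None):
    """Build a HarmonizedSet directly from effect arrays."""
    J = len(beta_x)
    if snps is None:
        snps = [f"rs{i + 1}" for i in range(J)]
    rows = pd.DataFrame(
        {
            "SNP": snps,
            "beta_x": np.asarray(beta_x, dtype=float),
            "se_x": np.asarray(se_x, dtype=float),
            "beta_y": np.asarray(beta_y, dtype=float),
            "se_y": np.asarray(se_y, dtype=float),
            "eaf_x": 0.3,
            "eaf_y": 0.3,
        }
    )
    return HarmonizedSet("exposure", "outcome", rows)


@pytest.fixture
def three_snp_harmonized():
    return make_harmonized(
        beta_x=[0.1, 0.2, 0.15],
        se_x=[0.005, 0.005, 0.005],
        beta_y=[0.02, 0.05, 0.03],
        se_y=[0.01, 0.02, 0.015],
    )


@pytest.fixture
def noisy_harmonized():
    """A 30-SNP harmonized set with a true slope of 0.25."""
    rng = np.random.default_rng(42)
    J = 30
    gx = rng.uniform(0.05, 0.2, J)
    se_x = np.full(J, 0.004)
    se_y = rng.uniform(0.008, 0.02, J)
    bx = rng.normal(gx, se_x)
    by = rng.normal(0.25 * gx, se_y)
    return make_harmonized(bx, se_x, by, se_y)
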