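import numpy as np
import pandas as pd
import pytest

from mrkit import (
    GwasSummary,
    HarmonizationError,
    SummaryFormatError,
    ValidationError,
    harmonize,
    is_palindromic,
    read_summary_stats,
    write_summary_stats,
)
from conftest import make_summary


class TestReadWrite:
    def test_round_trip_is_identity(self, tmp_path):
        g = make_summary(
            "trait",
            ["rs1", "rs2", "rs3"],
            betas=[0.1, -0.27, 0.031415926535],
            ses=[0.01, 0.05, 0.004],
            effect_alleles=["A", "C", "T"],
            other_alleles=["G", "T", "C"],
            eafs=[0.3, 0.51, 0.12],
        )
        p = write_summary_stats(g, tmp_path / "t.tsv")
        back = read_summary_stats(p, trait_label="trait")
        pd.testing.assert_frame_equal(back.records, g.records)

    def test_three_row_table_reads_as_three_records(self, tmp_path):
        g = make_summary("t", ["rs1", "rs2", "rs3"], [0.1, 0.2, 0.3], [0.01] * 3)
        p = write_summary_stats(g, tmp_path / "t.tsv")
        assert p.read_text().count("\n") == 4  # header + 3 rows
        assert len(read_summary_stats(p)) == 3

    def test_empty_table_writes_header_only(self, tmp_path):
        g = GwasSummary("empty", pd.DataFrame(columns=["SNP"]))
        p = write_summary_stats(g, tmp_path / "e.tsv")
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("SNP\teffect_allele")

    def test_zero_se_rejected_naming_snp(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "SNP\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tG\t0.1\t0.01\t0.001\n"
            "rs2\tA\tG\t0.1\t0.0\t0.001\n"
        )
        with pytest.raises(ValidationError, match="rs2"):
            read_summary_stats(p)
        lenient = read_summary_stats(p, strict=False)
        assert lenient.records["SNP"].tolist() == ["rs1"]

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\teffect_allele\tother_allele\tbeta\tpval\nrs1\tA\tG\t0.1\t0.01\n")
        with pytest.raises(SummaryFormatError, match="'se'"):
            read_summary_stats(p)

    def test_dialect_maps_nonstandard_names(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "rsid,ea,oa,b,stderr,p\nrs1,a,g,0.1,0.01,1e-9\n"
        )
        g = read_summary_stats(
            p,
            dialect={
                "SNP": "rsid", "effect_allele": "ea", "other_allele": "oa",
                "beta": "b", "se": "stderr", "pval": "p",
            },
        )
        assert g.records["effect_allele"].tolist() == ["A"]  # upper-cased

    def test_indel_alleles_rejected(self):
        with pytest.raises(ValidationError, match="single-nucleotide"):
            make_summary("t", ["rs1"], [0.1], [0.01], effect_alleles=["AT"], other_alleles=["G"])


@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("A", "C", False), ("T", "C", False)],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def _pair(eaf_x=0.3, eaf_y=0.3, out_ea="A", out_oa="G", out_beta=0.2,
          exp_ea="A", exp_oa="G", pal=False):
    if pal:
        exp_ea, exp_oa = "A", "T"
        if out_ea == "A" and out_oa == "G":
            out_ea, out_oa = "A", "T"
    exposure = make_summary("x", ["rs1"], [0.1], [0.01],
                            effect_alleles=[exp_ea], other_alleles=[exp_oa],
                            eafs=[eaf_x])
    outcome = make_summary("y", ["rs1"], [out_beta], [0.02],
                           effect_alleles=[out_ea], other_alleles=[out_oa],
                           eafs=[eaf_y])
    return exposure, outcome


class TestHarmonize:
    def test_swapped_alleles_negate_beta(self):
        exposure, outcome = _pair(out_ea="G", out_oa="A")
        h = harmonize(exposure, outcome)
        assert h.rows["beta_y"].iloc[0] == pytest.approx(-0.2)
        assert h.rows["eaf_y"].iloc[0] == pytest.approx(0.7)

    def test_aligned_pair_is_unchanged(self):
        exposure, outcome = _pair()
        h = harmonize(exposure, outcome)
        assert h.rows["beta_y"].iloc[0] == pytest.approx(0.2)

    def test_missing_in_outcome_excluded(self):
        exposure = make_summary("x", ["rs1", "rs2"], [0.1, 0.1], [0.01, 0.01])
        outcome = make_summary("y", ["rs1"], [0.2], [0.02])
        h = harmonize(exposure, outcome)
        assert h.n_snp == 1
        assert h.exclusions.iloc[0].tolist() == ["rs2", "missing_in_outcome"]

    def test_incompatible_alleles_excluded(self):
        exposure2 = make_summary("x", ["rs1", "rs2"], [0.1, 0.1], [0.01, 0.01])
        outcome2 = make_summary(
            "y", ["rs1", "rs2"], [0.2, 0.2], [0.02, 0.02],
            effect_alleles=["A", "C"], other_alleles=["G", "T"],
        )
        h = harmonize(exposure2, outcome2)
        assert h.n_snp == 1
        assert (h.exclusions["reason"] == "incompatible_alleles").sum() == 1

    def test_palindrome_exclude_all(self):
        exposure, outcome = _pair(pal=True, eaf_x=0.1, eaf_y=0.1)
        with pytest.raises(HarmonizationError):
            harmonize(exposure, outcome, palindrome_policy="exclude_all")

    def test_palindrome_ambiguous_near_half_frequency(self):
        exposure, outcome = _pair(pal=True, eaf_x=0.5, eaf_y=0.5)
        with pytest.raises(HarmonizationError, match="no harmonizable"):
            harmonize(exposure, outcome)

    def test_palindrome_missing_eaf_is_ambiguous(self):
        exposure, outcome = _pair(pal=True)
        exposure.records.loc[0, "eaf"] = np.nan
        with pytest.raises(HarmonizationError):
            harmonize(exposure, outcome)

    def test_palindrome_resolved_by_frequency_agreement(self):
        exposure, outcome = _pair(pal=True, eaf_x=0.2, eaf_y=0.25)
        h = harmonize(exposure, outcome)
        assert h.rows["beta_y"].iloc[0] == pytest.approx(0.2)

    def test_palindrome_strand_flip_detected_by_frequency(self):
        # outcome frequency on the other side of 0.5: opposite strand
        exposure, outcome = _pair(pal=True, eaf_x=0.2, eaf_y=0.8)
        h = harmonize(exposure, outcome)
        assert h.rows["beta_y"].iloc[0] == pytest.approx(-0.2)

    def test_partition_invariant(self):
        from mrkit import SimConfig, simulate_pair

        cfg = SimConfig(J=40, n_palindromic=5, n_missing_in_outcome=3)
        exposure, outcome, _, _ = simulate_pair(cfg, seed=9)
        h = harmonize(exposure, outcome)
        assert h.n_snp + len(h.exclusions) == len(exposure)
        assert set(h.rows["SNP"]) | set(h.exclusions["snp_id"]) == set(
            exposure.records["SNP"]
        )

    def test_idempotence_on_aligned_pair(self):
        from mrkit import SimConfig, simulate_pair

        exposure, outcome, _, _ = simulate_pair(SimConfig(J=25), seed=4)
        h1 = harmonize(exposure, outcome)
        realigned = make_summary(
            "y2",
            h1.rows["SNP"].tolist(),
            h1.rows["beta_y"].tolist(),
            h1.rows["se_y"].tolist(),
            effect_alleles=exposure.subset(h1.rows["SNP"].tolist()).records["effect_allele"].tolist(),
            other_alleles=exposure.subset(h1.rows["SNP"].tolist()).records["other_allele"].tolist(),
            eafs=h1.rows["eaf_y"].tolist(),
        )
        h2 = harmonize(exposure.subset(h1.rows["SNP"].tolist()), realigned)
        np.testing.assert_allclose(h2.rows["beta_y"], h1.rows["beta_y"])

    def test_label_symmetry(self):
        """Relabelling every outcome allele pair (beta negated, eaf
        complemented) describes the same data and harmonizes identically."""
        from mrkit import SimConfig, simulate_pair

        exposure, outcome, _, _ = simulate_pair(SimConfig(J=30, n_palindromic=4), seed=13)
        h1 = harmonize(exposure, outcome)
        flipped = outcome.records.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1.0 - flipped["eaf"]
        h2 = harmonize(exposure, GwasSummary(outcome.trait_label, flipped))
        pd.testing.assert_frame_equal(h1.rows, h2.rows)
        pd.testing.assert_frame_equal(h1.exclusions, h2.exclusions)
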