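"""Summary-statistic reading/validation and allele harmonization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from triopgs.sumstats_io import (
    GenotypePanel,
    SummaryStats,
    SumstatsError,
    harmonize,
    read_genotypes,
    read_sumstats,
    write_pedigree,
    write_traw,
    write_vcf,
)


def _write_sumstats_file(tmp_path, rows, header="variant_id\tchrom\tpos\teffect_allele\tother_allele\tweight\tpvalue\teaf"):
    path = tmp_path / "ss.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadSumstats:
    def test_well_formed_rows_all_retained(self, tmp_path):
        path = _write_sumstats_file(tmp_path, [
            "rs1\t1\t100\tA\tG\t0.2\t0.01\t0.3",
            "rs2\t1\t200\tC\tT\t-0.1\t0.5\t0.4",
            "rs3\t2\t300\tG\tA\t0.05\t1.0\t0.2",
        ])
        ss = read_sumstats(path)
        assert len(ss) == 3
        assert list(ss.table["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_zero_pvalue_row_dropped(self, tmp_path):
        path = _write_sumstats_file(tmp_path, [
            "rs1\t1\t100\tA\tG\t0.2\t0.0\t0.3",
            "rs2\t1\t200\tC\tT\t-0.1\t0.5\t0.4",
        ])
        ss = read_sumstats(path)
        assert list(ss.table["variant_id"]) == ["rs2"]

    def test_or_scale_log_transformed(self, tmp_path):
        path = _write_sumstats_file(tmp_path, [
            "rs1\t1\t100\tA\tG\t1.0\t0.01\t0.3",
            "rs2\t1\t200\tC\tT\t2.0\t0.5\t0.4",
        ])
        ss = read_sumstats(path, scale="OR")
        w = ss.table.set_index("variant_id")["weight"]
        assert w["rs1"] == 0.0
        assert w["rs2"] == pytest.approx(np.log(2.0))

    def test_missing_column_is_fatal_and_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant_id\tchrom\tpos\teffect_allele\tother_allele\tweight\nrs1\t1\t100\tA\tG\t0.2\n")
        with pytest.raises(SumstatsError, match="pvalue"):
            read_sumstats(path)

    def test_all_rows_invalid_is_fatal(self, tmp_path):
        path = _write_sumstats_file(tmp_path, ["rs1\t1\t100\tA\tA\t0.2\t0.01\t0.3"])
        with pytest.raises(SumstatsError):
            read_sumstats(path)

    def test_column_map_remaps_file_columns(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\tP\nrs1\t1\t100\tA\tG\t0.2\t0.01\n")
        ss = read_sumstats(path, column_map={
            "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
            "effect_allele": "A1", "other_allele": "A2",
            "weight": "BETA", "pvalue": "P",
        })
        assert len(ss) == 1 and np.isnan(ss.table["eaf"].iat[0])


class TestHarmonize:
    @pytest.mark.parametrize(
        "eff,oth,expected_flag,expected_sign",
        [
            ("A", "G", "direct", 1),                       # effect == alt
            ("G", "A", "allele_swapped", -1),              # effect == ref
            ("T", "C", "strand_flipped", 1),               # complements to (A, G)
            ("C", "T", "strand_flipped_and_swapped", -1),
        ],
    )
    def test_allele_alignment_sign_rules(self, tiny_panel, eff, oth, expected_flag, expected_sign):
        df = pd.DataFrame({
            "variant_id": ["rs1"], "chrom": ["1"], "pos": [100],
            "effect_allele": [eff], "other_allele": [oth],
            "weight": [0.7], "pvalue": [0.01], "eaf": [0.3],
        })
        hw = harmonize(SummaryStats.from_frame(df), tiny_panel, maf_threshold=0.0)
        assert hw.flag[0] == expected_flag
        assert hw.weight[0] == pytest.approx(expected_sign * 0.7)

    def test_ambiguous_strand_dropped_by_default(self, tiny_panel):
        df = pd.DataFrame({
            "variant_id": ["rs3", "rs1"], "chrom": ["1", "1"], "pos": [300, 100],
            "effect_allele": ["A", "A"], "other_allele": ["T", "G"],
            "weight": [0.5, 0.2], "pvalue": [0.01, 0.01], "eaf": [0.5, 0.3],
        })
        ss = SummaryStats.from_frame(df)
        hw = harmonize(ss, tiny_panel, maf_threshold=0.0)
        assert hw.counts["n_dropped_ambiguous"] == 1 and len(hw) == 1
        hw_keep = harmonize(ss, tiny_panel, maf_threshold=0.0, drop_ambiguous=False)
        assert len(hw_keep) == 2

    def test_maf_filter_strict(self, tiny_panel):
        # rs5 panel dosages (0,1,0) -> af 1/6 ~ 0.167
        df = pd.DataFrame({
            "variant_id": ["rs5"], "chrom": ["1"], "pos": [500],
            "effect_allele": ["G"], "other_allele": ["A"],
            "weight": [0.4], "pvalue": [0.01], "eaf": [0.2],
        })
        ss = SummaryStats.from_frame(df)
        hw = harmonize(ss, tiny_panel, maf_threshold=0.1)
        assert len(hw) == 1
        with pytest.raises(SumstatsError):
            harmonize(ss, tiny_panel, maf_threshold=0.5)

    def test_no_overlap_is_fatal(self, tiny_panel):
        df = pd.DataFrame({
            "variant_id": ["rs99"], "chrom": ["9"], "pos": [9],
            "effect_allele": ["A"], "other_allele": ["G"],
            "weight": [0.4], "pvalue": [0.01], "eaf": [0.2],
        })
        with pytest.raises(SumstatsError):
            harmonize(SummaryStats.from_frame(df), tiny_panel)

    def test_irreconcilable_alleles_dropped_with_flag(self, tiny_panel):
        df = pd.DataFrame({
            "variant_id": ["rs1", "rs2"], "chrom": ["1", "1"], "pos": [100, 200],
            "effect_allele": ["A", "A"], "other_allele": ["C", "G"],
            "weight": [0.4, 0.1], "pvalue": [0.01, 0.02], "eaf": [0.2, 0.3],
        })
        hw = harmonize(SummaryStats.from_frame(df), tiny_panel, maf_threshold=0.0)
        assert hw.counts["n_dropped_unmatched"] == 1
        assert "unmatched_alleles" in set(hw.report["flag"])

    def test_report_counts_conserve_input(self, tiny_panel, tiny_sumstats):
        hw = harmonize(tiny_sumstats, tiny_panel, maf_threshold=0.1)
        c = hw.counts
        assert c["n_input"] == (
            c["n_retained"] + c["n_dropped_maf"] + c["n_dropped_ambiguous"]
            + c["n_dropped_unmatched"] + c["n_dropped_no_overlap"]
        )

    def test_harmonization_idempotent(self, tiny_panel, tiny_sumstats):
        """Re-expressing aligned weights as alt/ref sumstats reproduces them."""
        hw = harmonize(tiny_sumstats, tiny_panel, maf_threshold=0.0)
        pv = tiny_panel.variants.iloc[hw.variant_index]
        re_ss = SummaryStats.from_frame(pd.DataFrame({
            "variant_id": pv["variant_id"].to_numpy(),
            "chrom": pv["chrom"].to_numpy(), "pos": pv["pos"].to_numpy(),
            "effect_allele": pv["alt"].to_numpy(), "other_allele": pv["ref"].to_numpy(),
            "weight": hw.weight, "pvalue": hw.pvalue, "eaf": np.nan,
        }))
        hw2 = harmonize(re_ss, tiny_panel, maf_threshold=0.0)
        np.testing.assert_array_equal(hw2.variant_index, hw.variant_index)
        np.testing.assert_allclose(hw2.weight, hw.weight, rtol=0, atol=0)
        assert all(f == "direct" for f in hw2.flag)

    def test_swapped_weight_scores_like_swapped_dosage(self, tiny_panel):
        """Per-variant: scoring a swapped weight equals scoring 2-d with the original."""
        for j, (ref, alt) in enumerate(zip(tiny_panel.variants["ref"], tiny_panel.variants["alt"])):
            w = 0.3 + 0.1 * j
            df = pd.DataFrame({
                "variant_id": [tiny_panel.variants["variant_id"].iat[j]],
                "chrom": ["1"], "pos": [tiny_panel.variants["pos"].iat[j]],
                "effect_allele": [ref], "other_allele": [alt],
                "weight": [w], "pvalue": [0.01], "eaf": [0.5],
            })
            hw = harmonize(SummaryStats.from_frame(df), tiny_panel,
                           maf_threshold=0.0, drop_ambiguous=False)
            d = tiny_panel.dosages[:, j]
            np.testing.assert_allclose(hw.weight[0] * d, w * (2 - d) - 2 * w)

    @settings(derandomize=True, max_examples=30, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(weights=st.lists(st.floats(-2, 2, allow_nan=False), min_size=5, max_size=5))
    def test_alignment_preserves_weight_magnitude(self, tiny_panel, tiny_sumstats, weights):
        ss = SummaryStats(tiny_sumstats.table.assign(weight=weights))
        hw = harmonize(ss, tiny_panel, maf_threshold=0.0)
        in_mag = ss.table.set_index("variant_id")["weight"].abs()
        for idx, w in zip(hw.variant_index, hw.weight):
            vid = tiny_panel.variants["variant_id"].iat[idx]
            assert abs(w) == pytest.approx(in_mag[vid])


class TestGenotypeIO:
    def test_traw_roundtrip_preserves_panel(self, tiny_panel, tmp_path):
        write_traw(tiny_panel, tmp_path / "g.traw")
        write_pedigree(tiny_panel, tmp_path / "g.fam")
        panel, _ = read_genotypes(tmp_path / "g.traw", tmp_path / "g.fam")
        np.testing.assert_array_equal(panel.dosages, tiny_panel.dosages)
        assert list(panel.samples["role"]) == ["father", "mother", "proband"]
        assert panel.samples["complete_trio"].tolist() == [False, False, True]

    def test_vcf_roundtrip_preserves_panel(self, tiny_panel, tmp_path):
        write_vcf(tiny_panel, tmp_path / "g.vcf")
        write_pedigree(tiny_panel, tmp_path / "g.fam")
        panel, _ = read_genotypes(tmp_path / "g.vcf", tmp_path / "g.fam")
        np.testing.assert_array_equal(panel.dosages, tiny_panel.dosages)
        assert list(panel.variants["variant_id"]) == list(tiny_panel.variants["variant_id"])

    def test_single_genotyped_parent_keeps_proband_incomplete(self, tiny_panel, tmp_path):
        write_traw(tiny_panel, tmp_path / "g.traw")
        cols = ["family_id", "sample_id", "father_id", "mother_id", "sex", "role", "batch"]
        extra = pd.DataFrame(
            [["F2", "F2-PR", "F2-FA", "F2-MO", "1", "proband", "batch1"],
             ["F2", "F2-FA", "0", "0", "1", "father", "batch1"]],
            columns=cols,
        )
        fam = pd.concat([tiny_panel.samples[cols], extra])
        for c in ("father_id", "mother_id"):
            fam[c] = fam[c].replace({"": "0"})
        fam.to_csv(tmp_path / "g.fam", sep="\t", index=False, header=False)
        panel, _ = read_genotypes(tmp_path / "g.traw", tmp_path / "g.fam")
        # F2 members aren't genotyped -> excluded entirely
        assert set(panel.samples["sample_id"]) == {"F1-FA", "F1-MO", "F1-PR"}

    def test_incomplete_trio_flagged_not_dropped(self, tiny_panel, tmp_path):
        # remove the mother from both files: proband stays, flagged incomplete
        sub = GenotypePanel.from_parts(
            tiny_panel.samples.drop(1), tiny_panel.variants, tiny_panel.dosages[[0, 2]]
        )
        write_traw(sub, tmp_path / "g.traw")
        write_pedigree(sub, tmp_path / "g.fam")
        panel, _ = read_genotypes(tmp_path / "g.traw", tmp_path / "g.fam")
        pr = panel.samples.set_index("sample_id").loc["F1-PR"]
        assert pr["role"] == "proband" and not pr["complete_trio"]

    def test_nonbinary_phenotype_is_fatal(self, tiny_panel, tmp_path):
        write_traw(tiny_panel, tmp_path / "g.traw")
        write_pedigree(tiny_panel, tmp_path / "g.fam")
        (tmp_path / "phen.tsv").write_text("sample_id\tinsomnia\tage\nF1-PR\t2\t10\n")
        with pytest.raises(ValueError, match="insomnia"):
            read_genotypes(tmp_path / "g.traw", tmp_path / "g.fam", tmp_path / "phen.tsv")

    def test_maf_matches_dosage_recomputation(self, tiny_panel):
        af, maf = GenotypePanel.allele_frequencies(tiny_panel.dosages)
        np.testing.assert_allclose(tiny_panel.variants["maf"], maf, atol=1e-12)

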