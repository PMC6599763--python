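"""Genotype I/O, Hardy-Weinberg testing and QC filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hwe_enumeration_pvalue
from pcovr_gxe import (
    GenotypeMatrix,
    QcThresholds,
    SimulationConfig,
    apply_qc,
    hwe_exact_test,
    impute_and_standardize,
    read_genotypes,
    simulate_genotypes,
)
from pcovr_gxe.qc import write_tsv_dosage, write_vcf


def _fixture_matrix():
    cfg = SimulationConfig(
        n_subjects=60, n_snps=10, block_sizes=[5, 5], missing_genotype_rate=0.0, seed=42
    )
    gm, _ = simulate_genotypes(cfg)
    vals = gm.values.copy()
    vals[:3, 0] = np.nan  # one SNP with some missingness
    return GenotypeMatrix(vals, gm.subject_ids, gm.annotation)


class TestReading:
    def test_vcf_additive_coding(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        gm = read_genotypes(path, "vcf")
        # alt frequency 0.5: no flip; column is 0,1,2 in sample order
        assert gm.values[:, 0].tolist() == [0.0, 1.0, 2.0]

    def test_vcf_minor_allele_orientation(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n"
        )
        gm = read_genotypes(path, "vcf")
        # alt allele is the major allele -> codes flipped to count REF
        assert gm.values[:, 0].tolist() == [0.0, 0.0, 1.0]
        assert gm.annotation.loc[0, "ref"] == "G"

    def test_vcf_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="biallelic"):
            read_genotypes(path, "vcf")

    def test_tsv_preserves_missing_codes(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            "subject_id\trs1\trs2\nS1\t0\tNA\nS2\t1\t1\nS3\t2\t0\nS4\t1\t0\n"
        )
        gm = read_genotypes(path, "tsv_dosage")
        assert np.isnan(gm.values[0, 1])
        assert gm.values[1, 0] == 1.0

    def test_plink_raw_parses_counted_allele_headers(self, tmp_path):
        path = tmp_path / "g.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_G rs2_A\n"
            "F1 S1 0 0 1 -9 0 2\n"
            "F1 S2 0 0 2 -9 1 NA\n"
            "F2 S3 0 0 1 -9 2 1\n"
            "F2 S4 0 0 1 -9 1 1\n"
        )
        gm = read_genotypes(path, "plink_raw")
        assert gm.snp_ids == ["rs1", "rs2"]
        assert np.isnan(gm.values[1, 1])

    def test_duplicate_snp_ids_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("subject_id\trs1\trs1\nS1\t0\t1\nS2\t1\t1\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_genotypes(path, "tsv_dosage")

    @pytest.mark.parametrize("fmt,writer", [("tsv_dosage", write_tsv_dosage), ("vcf", write_vcf)])
    def test_round_trip(self, tmp_path, fmt, writer):
        cfg = SimulationConfig(
            n_subjects=40, n_snps=8, block_sizes=[4, 4], missing_genotype_rate=0.1, seed=6
        )
        gm, _ = simulate_genotypes(cfg)
        vals = gm.values.copy()
        vals[np.random.default_rng(0).random(vals.shape) < 0.1] = np.nan
        gm = GenotypeMatrix(vals, gm.subject_ids, gm.annotation)
        path = tmp_path / f"g.{fmt}"
        writer(gm, path)
        back = read_genotypes(path, fmt, annotation=gm.annotation)
        oriented = gm.orient_to_minor()
        assert np.array_equal(back.values, oriented.values, equal_nan=True)
        assert back.subject_ids == oriented.subject_ids


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((25, 50, 25), 1.0),  # modal heterozygote count
            ((100, 0, 0), 1.0),  # monomorphic: single configuration
        ],
    )
    def test_known_values(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_extreme_heterozygote_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_matches_enumeration_oracle_on_small_grid(self):
        # the full grid to total 60 runs in the acceptance suite
        for total in (7, 16, 33):
            for n2 in range(total + 1):
                for n1 in range(total - n2 + 1):
                    n0 = total - n2 - n1
                    p = hwe_exact_test(n2, n1, n0)
                    assert p == pytest.approx(
                        float(hwe_enumeration_pvalue(n2, n1, n0)), abs=1e-12
                    )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n2=st.integers(0, 80), n1=st.integers(0, 80), n0=st.integers(0, 80)
    )
    def test_pvalue_always_in_unit_interval(self, n2, n1, n0):
        if n2 + n1 + n0 == 0:
            with pytest.raises(ValueError):
                hwe_exact_test(n2, n1, n0)
        else:
            assert 0 < hwe_exact_test(n2, n1, n0) <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestApplyQc:
    def test_clean_fixture_passes_untouched(self):
        cfg = SimulationConfig(
            n_subjects=80, n_snps=10, block_sizes=[5, 5], maf_range=(0.2, 0.4),
            missing_genotype_rate=0.0, seed=8,
        )
        gm, _ = simulate_genotypes(cfg)
        out, report = apply_qc(gm)
        assert report.n_snps_out == 10
        assert report.n_subjects_out == 80
        assert report.removed_snps.empty

    def test_low_call_rate_snp_removed_with_reason(self):
        gm = _fixture_matrix()
        vals = gm.values.copy()
        vals[:10, 2] = np.nan  # 10/60 missing -> call rate 0.833
        gm = GenotypeMatrix(vals, gm.subject_ids, gm.annotation)
        out, report = apply_qc(gm, QcThresholds(snp_call_rate=0.95, subject_call_rate=0.5))
        removed = report.removed_snps
        assert (removed["reason"] == "call_rate").any()
        assert gm.snp_ids[2] in removed["snp_id"].tolist()

    def test_removal_counts_match_independent_recount(self):
        cfg = SimulationConfig(
            n_subjects=100, n_snps=30, block_sizes=[30], missing_genotype_rate=0.04, seed=13
        )
        gm, _ = simulate_genotypes(cfg)
        vals = gm.values.copy()
        rng = np.random.default_rng(13)
        vals[rng.random(vals.shape) < 0.04] = np.nan
        gm = GenotypeMatrix(vals, gm.subject_ids, gm.annotation)
        th = QcThresholds(snp_call_rate=0.97, subject_call_rate=0.90, maf_min=0.05, hwe_alpha=0.0)
        out, report = apply_qc(gm, th)
        # independent recount, same filter order
        keep_subj = (~np.isnan(vals)).mean(axis=1) >= 0.90
        v = vals[keep_subj]
        keep_cr = (~np.isnan(v)).mean(axis=0) >= 0.97
        v = v[:, keep_cr]
        freq = np.nanmean(v, axis=0) / 2
        keep_maf = np.minimum(freq, 1 - freq) >= 0.05
        expected_out = int(keep_maf.sum())
        assert report.n_snps_out == expected_out
        assert report.n_subjects_out == int(keep_subj.sum())

    def test_conservation_removed_plus_retained(self):
        gm = _fixture_matrix()
        out, report = apply_qc(gm, QcThresholds(maf_min=0.10))
        assert report.n_snps_out + len(report.removed_snps) == report.n_snps_in
        assert report.n_subjects_out + len(report.removed_subjects) == report.n_subjects_in

    def test_idempotent_second_pass(self):
        gm = _fixture_matrix()
        th = QcThresholds(maf_min=0.05)
        out1, _ = apply_qc(gm, th)
        out2, report2 = apply_qc(out1, th)
        assert report2.removed_snps.empty
        assert np.array_equal(out1.values, out2.values, equal_nan=True)

    def test_everything_missing_raises(self):
        vals = np.full((5, 3), np.nan)
        gm = GenotypeMatrix(vals, [f"S{i}" for i in range(5)],
                            pd.DataFrame({"snp_id": ["a", "b", "c"], "chrom": "1",
                                          "pos": [1, 2, 3], "gene": "g", "ref": "A", "alt": "G"}))
        with pytest.raises(ValueError, match="QC"):
            apply_qc(gm)


class TestImputeStandardize:
    def test_mean_imputation_value(self):
        vals = np.array([[0.0], [1.0], [2.0], [np.nan]])
        gm = GenotypeMatrix(vals, ["a", "b", "c", "d"],
                            pd.DataFrame({"snp_id": ["rs1"], "chrom": "1", "pos": [1],
                                          "gene": "g", "ref": "A", "alt": "G"}))
        z, scale = impute_and_standardize(gm)
        # missing -> observed mean 1.0 -> exactly at the column mean -> z = 0
        assert z[3, 0] == pytest.approx(0.0, abs=1e-12)

    def test_columns_standardized(self):
        cfg = SimulationConfig(n_subjects=120, n_snps=8, block_sizes=[8],
                               missing_genotype_rate=0.05, seed=4)
        gm, _ = simulate_genotypes(cfg)
        vals = gm.values.copy()
        vals[np.random.default_rng(4).random(vals.shape) < 0.05] = np.nan
        gm = GenotypeMatrix(vals, gm.subject_ids, gm.annotation)
        z, _ = impute_and_standardize(gm)
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        assert np.abs(z.std(axis=0) - 1).max() < 1e-12

    def test_zero_variance_rejected(self):
        vals = np.array([[1.0], [1.0], [1.0]])
        gm = GenotypeMatrix(vals, ["a", "b", "c"],
                            pd.DataFrame({"snp_id": ["rs1"], "chrom": "1", "pos": [1],
                                          "gene": "g", "ref": "A", "alt": "G"}))
        with pytest.raises(ValueError, match="zero-variance"):
            impute_and_standardize(gm)

    def test_orientation_invariant_maf_below_half(self):
        cfg = SimulationConfig(n_subjects=300, n_snps=12, block_sizes=[12],
                               maf_range=(0.35, 0.5), missing_genotype_rate=0.0, seed=19)
        gm, _ = simulate_genotypes(cfg)
        oriented = gm.orient_to_minor()
        assert (oriented.maf() <= 0.5 + 1e-12).all()
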