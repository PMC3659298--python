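"""Catalog/genotype/phenotype I-O, validation, and leak-free imputation."""

import numpy as np
import pandas as pd
import pytest

from lipidprs import (
    GenotypeMatrix,
    LongCohort,
    MarkerCatalogEntry,
    PhenotypeTable,
    ValidationError,
    impute_missing_dosages,
    per_trait_counts,
    read_catalog,
    read_genotypes,
    read_phenotypes,
    write_catalog,
    write_genotypes,
    write_genotypes_vcf,
    write_phenotypes,
)

CATALOG_HEADER = "marker_id\teffect_allele\tother_allele\tweight_mg_dl\ttrait\tstudy_n\tsource\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestCatalog:
    def test_two_valid_rows_parsed_with_counts(self, tmp_path):
        p = _write(
            tmp_path, "cat.tsv",
            CATALOG_HEADER
            + "rs1\tA\tG\t0.5\tHDL\t1000\tstudyA\n"
            + "rs2\tC\tT\t-1.2\tTG\t2000\tstudyB\n",
        )
        entries = read_catalog(p)
        assert len(entries) == 2
        assert per_trait_counts(entries) == {"HDL": 1, "LDL": 0, "TC": 0, "TG": 1}

    @pytest.mark.parametrize(
        "row",
        [
            "rs1\tA\tG\t0.5\tVLDL\t1000\ts",      # unknown trait
            "rs1\tX\tG\t0.5\tHDL\t1000\ts",       # bad allele code
            "rs1\tA\tA\t0.5\tHDL\t1000\ts",       # identical alleles
            "rs1\tA\tG\tlots\tHDL\t1000\ts",      # non-numeric weight
            "rs1\tA\tG\t0.5\tHDL\t-5\ts",         # non-positive study n
        ],
    )
    def test_malformed_rows_rejected_naming_row(self, tmp_path, row):
        p = _write(tmp_path, "cat.tsv", CATALOG_HEADER + row + "\n")
        with pytest.raises(ValidationError, match="row 0"):
            read_catalog(p)

    def test_non_mgdl_units_column_rejected(self, tmp_path):
        p = _write(
            tmp_path, "cat.tsv",
            CATALOG_HEADER.rstrip("\n") + "\tunits\n"
            + "rs1\tA\tG\t0.05\tHDL\t1000\ts\tmmol/L\n",
        )
        with pytest.raises(ValidationError, match="mg/dL"):
            read_catalog(p)

    def test_roundtrip_and_duplicate_preservation(self, tmp_path):
        entries = [
            MarkerCatalogEntry("rs1", "A", "G", 0.123456789, "HDL", 1000),
            MarkerCatalogEntry("rs1", "A", "G", 0.3, "HDL", 5000),
            MarkerCatalogEntry("rs2", "C", "T", -2.5, "LDL", 900, "x"),
        ]
        p = tmp_path / "cat.tsv"
        write_catalog(entries, p)
        back = read_catalog(p)
        assert [e.marker_id for e in back] == ["rs1", "rs1", "rs2"]
        assert back[0].weight == entries[0].weight  # bit-identical

    def test_counts_invariant_to_row_order(self):
        entries = [
            MarkerCatalogEntry("rs1", "A", "G", 0.5, "HDL", 10),
            MarkerCatalogEntry("rs2", "C", "T", 0.5, "TC", 10),
            MarkerCatalogEntry("rs3", "A", "C", 0.5, "HDL", 10),
        ]
        assert per_trait_counts(entries) == per_trait_counts(entries[::-1])


class TestGenotypes:
    def test_tsv_roundtrip_bit_identical(self, tmp_path):
        g = GenotypeMatrix(
            ["s1", "s2"], ["rs1", "rs2"],
            np.array([[0.123456789012345, 2.0], [np.nan, 1.0]]),
        )
        p = tmp_path / "g.tsv"
        write_genotypes(g, p)
        back = read_genotypes(p, format="tsv")
        assert back.subject_ids == g.subject_ids
        assert np.array_equal(back.dosage, g.dosage, equal_nan=True)

    def test_tsv_cell_parses_to_float(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "subject_id\trs1\ns1\t2\n")
        g = read_genotypes(p, format="tsv")
        assert g.dosage[0, 0] == 2.0

    def test_out_of_range_dosage_rejected(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "subject_id\trs1\ns1\t2.5\n")
        with pytest.raises(ValidationError, match=r"\[0,2\]"):
            read_genotypes(p, format="tsv")

    def test_vcf_orientation_and_roundtrip(self, tmp_path):
        # rs1: effect = ALT, rs2: effect = REF (flip 2 - d)
        catalog = [
            MarkerCatalogEntry("rs1", "G", "A", 0.5, "HDL", 10),
            MarkerCatalogEntry("rs2", "C", "T", 0.5, "HDL", 10),
        ]
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\n"
        )
        p = _write(tmp_path, "in.vcf", vcf)
        g = read_genotypes(p, format="vcf", catalog=catalog)
        # rs1 effect=ALT: 0/1 -> 1, 1/1 -> 2; rs2 effect=REF: 0/1 -> 1, 0/0 -> 2
        assert g.dosage[0, 0] == 1.0 and g.dosage[1, 0] == 2.0
        assert g.dosage[0, 1] == 1.0 and g.dosage[1, 1] == 2.0
        # effect + other dosages sum to 2 for complete diploid calls
        flipped = [
            MarkerCatalogEntry("rs1", "A", "G", 0.5, "HDL", 10),
            MarkerCatalogEntry("rs2", "T", "C", 0.5, "HDL", 10),
        ]
        g2 = read_genotypes(p, format="vcf", catalog=flipped)
        assert np.allclose(g.dosage + g2.dosage, 2.0)
        # write our own DS-based VCF and read it back
        out = tmp_path / "out.vcf"
        write_genotypes_vcf(g, catalog, out)
        back = read_genotypes(out, format="vcf", catalog=catalog)
        assert np.allclose(back.dosage, g.dosage, atol=1e-9)

    def test_multiallelic_marker_skipped(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\n"
        )
        p = _write(tmp_path, "m.vcf", vcf)
        g = read_genotypes(
            p, format="vcf",
            catalog=[MarkerCatalogEntry("rs2", "T", "C", 0.5, "HDL", 10)],
        )
        assert g.marker_ids == ["rs2"]


class TestPhenotypes:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["subject_id", "age", "sex", "bmi", "hdl", "ldl", "tc", "tg"]
        )

    def test_three_rows_one_subject(self):
        t = PhenotypeTable(self._table(
            [("s1", a, 0, 20.0, np.nan, 100.0, np.nan, np.nan) for a in (5, 8, 11)]
        ))
        assert t.visits_per_subject()["s1"] == 3

    def test_rows_sorted_by_subject_then_age(self):
        t = PhenotypeTable(self._table(
            [("s1", 11, 0, 20, np.nan, 1, np.nan, np.nan),
             ("s1", 5, 0, 20, np.nan, 2, np.nan, np.nan)]
        ))
        assert list(t.df["age"]) == [5, 11]

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "p.tsv", "subject_id\tage\tsex\tbmi\thdl\tldl\ttc\ttg\n")
        with pytest.raises(ValidationError, match="no observations"):
            read_phenotypes(p)

    @pytest.mark.parametrize("age,sex", [(-1.0, 0), (5.0, 2)])
    def test_invalid_age_or_sex_rejected(self, age, sex):
        with pytest.raises(ValidationError):
            PhenotypeTable(self._table(
                [("s1", age, sex, 20, np.nan, 1, np.nan, np.nan)]
            ))

    def test_roundtrip(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        p = tmp_path / "p.tsv"
        write_phenotypes(cohort.phenotypes, p)
        back = read_phenotypes(p)
        pd.testing.assert_frame_equal(back.df, cohort.phenotypes.df)


class TestImputation:
    def test_reference_mean_fills_missing(self):
        g = GenotypeMatrix(
            ["a", "b", "c"], ["rs1"], np.array([[0.0], [2.0], [np.nan]])
        )
        out = impute_missing_dosages(g, ["a", "b"])
        assert out.dosage[2, 0] == 1.0

    def test_no_missing_is_identity(self):
        g = GenotypeMatrix(["a", "b"], ["rs1"], np.array([[0.0], [2.0]]))
        out = impute_missing_dosages(g, ["a", "b"])
        assert np.array_equal(out.dosage, g.dosage)

    def test_heldout_subject_does_not_influence_imputed_value(self):
        # 4-subject toy: mean over reference {a,b,c} = (0+1+2)/3 = 1
        base = np.array([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0], [np.nan, 0.0]])
        g1 = GenotypeMatrix(["a", "b", "c", "d"], ["rs1", "rs2"], base)
        out1 = impute_missing_dosages(g1, ["a", "b", "c"])
        assert out1.dosage[3, 0] == 1.0
        # change the held-out subject's other dosages: imputation unchanged
        mutated = base.copy()
        mutated[3, 1] = 2.0
        g2 = GenotypeMatrix(["a", "b", "c", "d"], ["rs1", "rs2"], mutated)
        out2 = impute_missing_dosages(g2, ["a", "b", "c"])
        assert out2.dosage[3, 0] == out1.dosage[3, 0]

    def test_fully_missing_marker_in_reference_rejected(self):
        g = GenotypeMatrix(
            ["a", "b"], ["rs1"], np.array([[np.nan], [1.0]])
        )
        with pytest.raises(ValidationError, match="rs1"):
            impute_missing_dosages(g, ["a"])


class TestLongCohort:
    def test_phenotype_subject_without_genotype_rejected(self, small_cohort):
        cohort, _ = small_cohort
        geno = cohort.genotypes
        smaller = GenotypeMatrix(
            geno.subject_ids[:-1], geno.marker_ids, geno.dosage[:-1]
        )
        with pytest.raises(ValidationError, match="lack genotype"):
            LongCohort(cohort.phenotypes, smaller, list(cohort.catalog))

    def test_unresolvable_catalog_markers_dropped_with_record(self, small_cohort):
        cohort, _ = small_cohort
        extra = cohort.catalog + [
            MarkerCatalogEntry("rs_absent", "A", "G", 1.0, "LDL", 10)
        ]
        c2 = LongCohort(cohort.phenotypes, cohort.genotypes, extra)
        assert c2.dropped_markers == ["rs_absent"]
        assert all(e.marker_id != "rs_absent" for e in c2.catalog)
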