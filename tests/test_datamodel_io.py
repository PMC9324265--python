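import math

import numpy as np
import pytest

from mirpgs.datamodel import MISSING, GenotypeMatrix, SampleRecord, VariantRecord
from mirpgs.errors import (
    DosageValueError,
    UndefinedFrequencyError,
    UnsupportedRecordError,
    VcfParseError,
)
from mirpgs.io import (
    attach_phenotypes,
    read_dosage_tsv,
    read_phenotypes,
    read_vcf,
    write_dosage_tsv,
    write_phenotypes,
    write_vcf,
)
from conftest import make_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def write_text_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestVariantRecord:
    def test_rejects_equal_alleles(self):
        with pytest.raises(ValueError, match="identical"):
            VariantRecord("rs1", "1", 100, "A", "A")

    def test_rejects_nonpositive_position(self):
        with pytest.raises(ValueError, match="position"):
            VariantRecord("rs1", "1", 0, "A", "G")

    def test_swap_exchanges_alleles(self):
        v = VariantRecord("rs1", "1", 100, "A", "G").swapped()
        assert (v.effect_allele, v.other_allele) == ("G", "A")


class TestReadVcf:
    def test_gt_to_dosage_and_missing(self, tmp_path):
        # unphased het, phased hom-alt, missing call in one record
        body = "1\t100\trs1\tT\tC\t.\t.\t.\tGT\t0/1\t1|1\t./.\n"
        m = read_vcf(write_text_vcf(tmp_path / "a.vcf", body))
        assert m.n_samples == 3 and m.n_variants == 1
        g = m.dosage_vector("rs1")
        assert g[0] == 1.0 and g[1] == 2.0 and math.isnan(g[2])
        v = m.variant("rs1")
        # effect allele is ALT, other is REF
        assert (v.effect_allele, v.other_allele) == ("C", "T")
        assert (v.chrom, v.pos) == ("1", 100)

    def test_multiallelic_record_rejected_with_position(self, tmp_path):
        body = "1\t123\trs9\tA\tC,G\t.\t.\t.\tGT\t0/1\t0/0\t1/1\n"
        with pytest.raises(UnsupportedRecordError, match="1:123"):
            read_vcf(write_text_vcf(tmp_path / "m.vcf", body))

    def test_malformed_header_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(VcfParseError):
            read_vcf(str(bad))

    def test_vcf_tsv_round_trip_preserves_dosage_and_missingness(self, tmp_path):
        body = (
            "1\t100\trs1\tT\tC\t.\t.\t.\tGT\t0/1\t1|1\t./.\n"
            "1\t200\trs2\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        m1 = read_vcf(write_text_vcf(tmp_path / "a.vcf", body))
        write_dosage_tsv(m1, tmp_path / "a.tsv")
        m2 = read_dosage_tsv(tmp_path / "a.tsv", variants=m1.variants)
        assert np.array_equal(m1.dosages, m2.dosages, equal_nan=True)
        assert m1.rsids == m2.rsids

    def test_write_vcf_read_back_identity(self, tmp_path, tiny_matrix):
        write_vcf(tiny_matrix, tmp_path / "t.vcf")
        back = read_vcf(str(tmp_path / "t.vcf"))
        re = back.subset_variants(tiny_matrix.rsids)  # writer sorts by position
        assert np.array_equal(tiny_matrix.dosages, re.dosages, equal_nan=True)


class TestDosageTsv:
    def test_round_trip_3x2(self, tmp_path):
        m = make_matrix([[2, MISSING], [0, 1], [1, 2]])
        write_dosage_tsv(m, tmp_path / "d.tsv")
        back = read_dosage_tsv(tmp_path / "d.tsv", variants=m.variants)
        assert np.array_equal(m.dosages, back.dosages, equal_nan=True)
        assert back.sample_ids == m.sample_ids

    def test_invalid_cell_names_row_and_column(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("sample_id\trs1\ns1\t3\n")
        with pytest.raises(DosageValueError, match="rs1"):
            read_dosage_tsv(tmp_path / "bad.tsv")


class TestEffectAlleleFrequency:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0, 1, 2], 0.5),
            ([2, 2, 2, 2], 1.0),
            ([0, 1, MISSING, 2], 0.5),  # hand count over non-missing: 3/6
        ],
    )
    def test_frequency_examples(self, dosages, expected):
        m = make_matrix(np.array(dosages, dtype=float)[:, None])
        assert m.effect_allele_frequency("rs1") == pytest.approx(expected)

    def test_all_missing_raises(self):
        m = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(UndefinedFrequencyError):
            m.effect_allele_frequency("rs1")

    def test_effect_plus_other_frequency_is_one(self, default_sim):
        from mirpgs.orientation import dosage_flip

        for rsid in default_sim.rsids[:5]:
            f = default_sim.effect_allele_frequency(rsid)
            flipped = dosage_flip(default_sim, rsid)
            assert f + flipped.effect_allele_frequency(rsid) == pytest.approx(1.0)

    def test_group_subsets_partition_the_total(self, tiny_matrix):
        f_case = tiny_matrix.effect_allele_frequency("rs1", "case")
        f_ctrl = tiny_matrix.effect_allele_frequency("rs1", "control")
        assert f_case == pytest.approx(0.25)
        assert f_ctrl == pytest.approx(0.5)


class TestPhenotypes:
    def test_attach_round_trip(self, tmp_path, tiny_matrix):
        write_phenotypes(tiny_matrix, tmp_path / "p.tsv")
        pheno = read_phenotypes(tmp_path / "p.tsv")
        bare = tiny_matrix.with_samples(
            [SampleRecord(sample_id=s.sample_id) for s in tiny_matrix.samples]
        )
        attached = attach_phenotypes(bare, pheno)
        assert [s.status for s in attached.samples] == [
            s.status for s in tiny_matrix.samples
        ]

    def test_missing_status_rejected(self, tmp_path, tiny_matrix):
        write_phenotypes(tiny_matrix, tmp_path / "p.tsv")
        text = (tmp_path / "p.tsv").read_text().replace("case", "NA", 1)
        (tmp_path / "p2.tsv").write_text(text)
        with pytest.raises(DosageValueError, match="status"):
            attach_phenotypes(tiny_matrix, read_phenotypes(tmp_path / "p2.tsv"))


class TestGenotypeMatrix:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            GenotypeMatrix(
                np.zeros((2, 2)),
                [VariantRecord("rs1", "1", 1, "A", "G")],
                [SampleRecord("s1"), SampleRecord("s2")],
            )

    def test_invalid_dosage_value_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            make_matrix([[0, 3]])
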