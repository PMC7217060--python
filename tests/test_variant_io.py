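import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melith import simcase
from melith.cnahet import CNASegment
from melith.variant_io import (
    PresenceStatus,
    RegionCall,
    RegionCallMatrix,
    SomaticVariant,
    internal_to_seg,
    read_cohort_table,
    read_matrix_tsv,
    read_multisample_vcf,
    read_sample_sheet,
    read_segments,
    seg_to_internal,
    write_matrix_tsv,
    write_multisample_vcf,
    write_segments,
)


class TestSomaticVariant:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError, match="identical"):
            SomaticVariant("chr1", 10, "C", "C")

    def test_rejects_context_not_centred_on_ref(self):
        with pytest.raises(ValueError, match="middle base"):
            SomaticVariant("chr1", 10, "C", "T", tri_context="AAA")

    def test_rejects_nonpositive_position(self):
        with pytest.raises(ValueError, match="position"):
            SomaticVariant("chr1", 0, "C", "T")

    def test_indel_carries_no_context_constraint(self):
        v = SomaticVariant("chr1", 10, "CT", "C")
        assert not v.is_snv


class TestRegionCall:
    def test_vaf_definition(self):
        assert RegionCall(depth=100, alt_count=10).vaf == pytest.approx(0.10)

    def test_zero_depth_gives_zero_vaf(self):
        assert RegionCall(depth=0, alt_count=0).vaf == 0.0

    def test_alt_above_depth_rejected(self):
        with pytest.raises(ValueError):
            RegionCall(depth=5, alt_count=6)


class TestCoordinateConvention:
    @pytest.mark.parametrize("start1,end1,start0,end0", [
        (1, 1, 0, 1), (100, 200, 99, 200), (5, 5, 4, 5),
    ])
    def test_seg_conversion_both_ways(self, start1, end1, start0, end0):
        assert seg_to_internal(start1, end1) == (start0, end0)
        assert internal_to_seg(start0, end0) == (start1, end1)

    @given(st.integers(1, 10**8), st.integers(0, 10**6))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_identity(self, start1, length):
        end1 = start1 + length
        assert internal_to_seg(*seg_to_internal(start1, end1)) == (start1, end1)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            internal_to_seg(5, 5)


class TestVcf:
    def test_write_read_round_trip(self, tmp_path):
        config = simcase.SimConfig(seed=5, n_mutations=60, n_regions=4,
                                   n_insertions=2, n_deletions=2)
        matrix, _, _ = simcase.simulate_case(config)
        path = tmp_path / "case.vcf"
        write_multisample_vcf(matrix, path)
        back = read_multisample_vcf(path)
        assert back.regions == matrix.regions
        key = {v.key: i for i, v in enumerate(matrix.variants)}
        assert set(key) == {v.key for v in back.variants}
        for i2, v in enumerate(back.variants):
            i1 = key[v.key]
            assert np.array_equal(matrix.depth[i1], back.depth[i2])
            assert np.array_equal(matrix.alt[i1], back.alt[i2])
            assert v.tri_context == matrix.variants[i1].tri_context
        assert (back.status == PresenceStatus.INDETERMINATE).all()

    def test_multiallelic_record_splits_into_rows(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "chr1\t100\t.\tG\tA,T\t.\t.\t.\tDP:AD\t100:80,12,8\t90:90,0,0\t50:40,5,5\n"
            "chr1\t200\t.\tC\tT\t.\t.\t.\tDP:AD\t100:90,10\t80:80,0\t60:30,30\n"
        )
        m = read_multisample_vcf(vcf)
        assert (m.n_variants, m.n_regions) == (3, 3)
        alts = sorted((v.pos, v.alt) for v in m.variants)
        assert alts == [(100, "A"), (100, "T"), (200, "T")]
        i = next(k for k, v in enumerate(m.variants) if v.pos == 200)
        assert m.vaf[i, 0] == pytest.approx(0.10)

    def test_missing_format_fields_is_an_error(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tG\tA\t.\t.\t.\tDP\t100\n"
        )
        with pytest.raises(ValueError, match="DP/AD"):
            read_multisample_vcf(vcf)


class TestMatrixTsv:
    def test_round_trip_identity(self, tmp_path):
        config = simcase.SimConfig(seed=7, n_mutations=40, n_regions=3)
        matrix, _, _ = simcase.simulate_case(config)
        matrix.status[0, 0] = PresenceStatus.PRESENT
        matrix.status[1, 1] = PresenceStatus.ABSENT
        path = tmp_path / "m.tsv"
        write_matrix_tsv(matrix, path)
        assert read_matrix_tsv(path) == matrix


class TestSeg:
    def _segments(self):
        return [
            CNASegment("R1", "chr1", 0, 1000, 10, -0.5, "loss"),
            CNASegment("R1", "chr2", 500, 2500, 20, 0.3, "gain"),
            CNASegment("R2", "chr1", 0, 1000, 10, 0.01, "neutral"),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "s.seg"
        segs = self._segments()
        write_segments(segs, path)
        assert read_segments(path) == segs

    def test_duplicate_interval_rejected(self, tmp_path):
        path = tmp_path / "dup.seg"
        df = pd.DataFrame(
            [["R1", "chr1", 1, 100, 5, 0.1], ["R1", "chr1", 1, 100, 5, 0.2]],
            columns=["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"],
        )
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_segments(path)

    def test_zero_length_interval_rejected(self, tmp_path):
        path = tmp_path / "zero.seg"
        df = pd.DataFrame(
            [["R1", "chr1", 100, 99, 5, 0.1]],
            columns=["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"],
        )
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_segments(path)


class TestCohortTable:
    def test_missing_csd_class_column_is_schema_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        pd.DataFrame({"sample_id": ["S1"], "stage": ["in_situ"],
                      "gene": ["BRAF"], "protein_change": ["V600E"]}
                     ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="group"):
            read_cohort_table(path)

    def test_unknown_group_label_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        pd.DataFrame({"sample_id": ["S1"], "group": ["CSD_medium"],
                      "stage": ["in_situ"], "gene": [""], "protein_change": [""]}
                     ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="CSD"):
            read_cohort_table(path)

    def test_valid_table_round_trips(self, tmp_path):
        df = simcase.simulate_cohort(5, 5, seed=3)
        path = tmp_path / "cohort.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_cohort_table(path)
        assert set(back["sample_id"]) == set(df["sample_id"])
        assert (back["mutational_load"] >= 0).all()


class TestLociBed:
    def test_reads_named_intervals(self, tmp_path):
        from melith.variant_io import read_loci_bed

        path = tmp_path / "loci.bed"
        path.write_text("chr9\t2400000\t2600000\tCDKN2A\nchr2\t0\t100\tG1\n")
        df = read_loci_bed(path)
        assert list(df.columns) == ["chrom", "start", "end", "name"]
        assert df.iloc[0]["name"] == "CDKN2A"

    def test_empty_interval_rejected(self, tmp_path):
        from melith.variant_io import read_loci_bed

        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t100\tx\n")
        with pytest.raises(ValueError):
            read_loci_bed(path)


class TestSampleSheet:
    def test_duplicate_region_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        pd.DataFrame({"region_id": ["PT1", "PT1"], "kind": ["PT", "PT"]}
                     ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_sheet(path)

    def test_unknown_kind_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        pd.DataFrame({"region_id": ["PT1"], "kind": ["XX"]}
                     ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="kind"):
            read_sample_sheet(path)
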