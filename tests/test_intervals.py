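"""Interval model, overlap engine and file readers/writers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sesvlink.intervals import (
    GeneModel,
    GenomicInterval,
    ParseError,
    Sample,
    chrom_key,
    find_overlaps,
    interval_gap,
)
from sesvlink import io as sio
from sesvlink.sv import SVCall

# the two reference loci printed for the ERBB2 / HNF1beta neighbourhood
# (1-based inclusive 37,686,431-37,745,059 and 39,687,914-39,730,426)
ERBB2_IV = GenomicInterval("chr17", 37_686_430, 37_745_059)
HNF1B_IV = GenomicInterval("chr17", 39_687_913, 39_730_426)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", 10, 10), ("chr1", 10, 5), ("chr1", -1, 5), ("", 0, 5)],
    )
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_chr_prefix_normalization(self):
        assert chrom_key("chr17") == chrom_key("17")
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("1", 50, 150)
        assert a.intersection_length(b) == 50
        assert a.intersection_length(b, normalize=False) == 0


def _brute_force(set_a, set_b):
    out = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if chrom_key(a.chrom) == chrom_key(b.chrom):
                olen = min(a.end, b.end) - max(a.start, b.start)
                if olen >= 1:
                    out.append((i, j, olen))
    return sorted(out)


intervals_st = st.lists(
    st.tuples(
        st.sampled_from(["chr1", "chr2", "1"]),
        st.integers(0, 500),
        st.integers(1, 200),
    ).map(lambda t: GenomicInterval(t[0], t[1], t[1] + t[2])),
    max_size=30,
)


class TestFindOverlaps:
    def test_reference_loci_do_not_overlap(self):
        assert find_overlaps([ERBB2_IV], [HNF1B_IV]) == []

    def test_identical_intervals_overlap_fully(self):
        iv = GenomicInterval("chr5", 100, 350)
        assert find_overlaps([iv], [iv]) == [(0, 0, 250)]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(intervals_st, intervals_st)
    def test_matches_bruteforce_and_symmetry(self, set_a, set_b):
        got = find_overlaps(set_a, set_b)
        assert got == _brute_force(set_a, set_b)
        flipped = sorted((j, i, o) for i, j, o in find_overlaps(set_b, set_a))
        assert flipped == got


class TestIntervalGap:
    def test_reference_pair_gap_is_about_1p9_mb(self):
        gap = interval_gap(ERBB2_IV, HNF1B_IV)
        assert gap == 39_687_913 - 37_745_059 == 1_942_854
        assert round(gap / 1e6, 1) == 1.9

    def test_overlapping_and_abutting_gap_zero(self):
        a = GenomicInterval("chr1", 0, 100)
        assert interval_gap(a, GenomicInterval("chr1", 50, 150)) == 0
        assert interval_gap(a, GenomicInterval("chr1", 100, 150)) == 0

    def test_different_chrom_undefined(self):
        a = GenomicInterval("chr1", 0, 100)
        assert interval_gap(a, GenomicInterval("chr2", 0, 100)) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(intervals_st.filter(len), intervals_st.filter(len))
    def test_zero_gap_iff_overlap_or_abut(self, set_a, set_b):
        a, b = set_a[0], set_b[0]
        gap = interval_gap(a, b)
        if gap is None:
            return
        overlaps = bool(find_overlaps([a], [b]))
        abuts = a.end == b.start or b.end == a.start
        assert (gap == 0) == (overlaps or abuts)


class TestReadPeaks:
    def test_narrowpeak_field_mapping(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr17\t100\t200\tp1\t0\t.\t7.5\t-1\t-1\t-1\n")
        peaks = sio.read_peaks(str(p))
        assert peaks == [(GenomicInterval("chr17", 100, 200), 7.5)]

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert sio.read_peaks(str(p)) == []

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t50\t40\tx\t3\n")
        with pytest.raises(ParseError, match="line 1"):
            sio.read_peaks(str(p))

    def test_rows_sorted_by_position(self, tmp_path):
        p = tmp_path / "u.bed"
        p.write_text("chr2\t10\t20\tx\t1\nchr1\t5\t15\ty\t2\nchr1\t1\t4\tz\t3\n")
        peaks = sio.read_peaks(str(p))
        assert [(iv.chrom, iv.start) for iv, _ in peaks] == [
            ("chr1", 1), ("chr1", 5), ("chr2", 10)]


class TestSVReaders:
    def test_vcf_del_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1001\tsv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=5000\n"
        )
        (call,) = sio.read_sv_calls(str(p), "S1")
        assert call.sv_type == "DEL"
        assert call.bp1 == ("chr1", 1000)
        assert call.bp2 == ("chr1", 5000)

    def test_bedpe_tra_record(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t999\t1000\tchr2\t1999\t2000\tTRA\n")
        (call,) = sio.read_sv_calls(str(p), "S1", dialect="bedpe")
        assert call.sv_type == "TRA"
        assert call.bp1 == ("chr1", 999)
        assert call.bp2 == ("chr2", 1999)

    def test_unknown_svtype_skipped(self, tmp_path, caplog):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t10\t11\tchr1\t99\t100\tWEIRD\nchr1\t10\t11\tchr1\t99\t100\tDEL\n")
        calls = sio.read_sv_calls(str(p), "S1", dialect="bedpe")
        assert [c.sv_type for c in calls] == ["DEL"]

    def _random_calls(self, rng, n=10):
        calls = []
        for k in range(n):
            sv_type = rng.choice(["DEL", "DUP", "INV", "TRA", "INS"])
            p1 = int(rng.integers(100, 10_000))
            if sv_type == "TRA":
                bp2 = ("chr9", int(rng.integers(100, 10_000)))
            elif sv_type == "INS":
                bp2 = None
            else:
                bp2 = ("chr3", p1 + int(rng.integers(100, 5_000)))
            calls.append(SVCall(f"sv{k}", "S1", str(sv_type), ("chr3", p1), bp2,
                                quality=float(round(rng.uniform(10, 60), 1))))
        return calls

    @pytest.mark.parametrize("dialect", ["sv-vcf", "bedpe"])
    def test_roundtrip_identity(self, tmp_path, rng, dialect):
        calls = self._random_calls(rng)
        path = str(tmp_path / f"rt.{dialect}")
        if dialect == "sv-vcf":
            sio.write_sv_vcf(calls, path)
        else:
            sio.write_bedpe(calls, path)
        assert sio.read_sv_calls(path, "S1", dialect=dialect) == calls

    def test_tra_without_mate_rejected(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1001\tsv1\tN\t<TRA>\t.\tPASS\tSVTYPE=TRA\n"
        )
        with pytest.raises(ParseError, match="TRA"):
            sio.read_sv_calls(str(p), "S1")


class TestTables:
    def test_expression_shape_and_duplicates(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tS1\tS2\ng1\t1.0\t2.0\ng2\t3.5\t4.5\ng3\t0\t1\n")
        m = sio.read_expression(str(p))
        assert m.shape == (3, 2)
        p.write_text("gene_id\tS1\tS2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ParseError, match="duplicate gene"):
            sio.read_expression(str(p))

    def test_clinical_parsing(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("sample_id\tcohort\trfs_time\trfs_event\n"
                     "S1\tnon-CAGA\t24.5\tcensored\nS2\tCAGA\t\t\n")
        s1, s2 = sio.read_clinical(str(p))
        assert s1.rfs_time == 24.5 and s1.rfs_event is False
        assert s2.rfs_time is None and s2.rfs_event is None

    def test_minus_strand_tss_is_end_minus_one(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("gene_id\tsymbol\tchrom\tstart\tend\tstrand\n"
                     "g1\tG1\tchr1\t100\t500\t-\ng2\tG2\tchr1\t100\t500\t+\n")
        g1, g2 = sio.read_gene_models(str(p))
        assert g1.tss == 499
        assert g2.tss == 100

    def test_sample_requires_time_and_event_together(self):
        with pytest.raises(ValueError):
            Sample("S1", "CAGA", rfs_time=10.0)

    def test_cross_check_reports_missing_clinical(self, tmp_path):
        import pandas as pd

        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["S1", "S2"])
        missing = sio.cross_check_samples(expr, [Sample("S1", "CAGA")])
        assert missing == ["S2"]
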