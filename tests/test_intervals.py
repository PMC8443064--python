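"""Interval model, BED/BEDPE I/O and genome binning."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epm.intervals import (
    BedParseError,
    GenomeTable,
    GenomicInterval,
    Interaction,
    SchemaError,
    bin_genome,
    distance,
    overlaps,
    read_bed,
    read_bedpe,
    read_chrom_sizes,
    write_bed,
    write_bedpe,
)

from conftest import iv


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)

    def test_genome_table_validation(self):
        with pytest.raises(ValueError):
            GenomeTable({"chr1": 0})
        assert GenomeTable({"chr1": 10})["chr1"] == 10


class TestBedIO:
    def test_read_bed4(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tE3\n")
        (rec,) = read_bed(p)
        assert (rec.chrom, rec.start, rec.end, rec.name) == ("chr1", 0, 100, "E3")

    def test_roundtrip_bed6(self, tmp_path):
        records = [
            GenomicInterval("chr1", 0, 100, name="a", score="0", strand="+"),
            GenomicInterval("chr2", 50, 80, name="b", score="7", strand="-"),
        ]
        p = tmp_path / "rt.bed"
        write_bed(records, p)
        assert read_bed(p) == records

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match="bad.bed:2"):
            read_bed(p)

    def test_empty_and_counts(self, tmp_path):
        p = tmp_path / "x.bed"
        write_bed([], p)
        assert p.read_text() == ""
        write_bed([GenomicInterval("chr1", 0, 5)], p)
        assert len(p.read_text().splitlines()) == 1

    def test_min_cols_enforced(self, tmp_path):
        p = tmp_path / "n.bed"
        p.write_text("chr1\t0\t100\n")
        with pytest.raises(BedParseError):
            read_bed(p, min_cols=4)


class TestBedpeIO:
    HEADER = "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tlnP\tFDR\n"

    def test_read_single(self, tmp_path):
        p = tmp_path / "i.bedpe"
        p.write_text(self.HEADER + "chr1\t0\t5000\tchr1\t50000\t55000\ti1\t-150\t0\n")
        (rec,) = read_bedpe(p)
        assert rec.anchor1 == GenomicInterval("chr1", 0, 5000)
        assert rec.anchor2 == GenomicInterval("chr1", 50000, 55000)
        assert rec.ln_p == -150 and rec.fdr == 0

    def test_empty_with_header(self, tmp_path):
        p = tmp_path / "e.bedpe"
        p.write_text(self.HEADER)
        assert read_bedpe(p) == []

    def test_missing_fdr_column(self, tmp_path):
        p = tmp_path / "m.bedpe"
        p.write_text("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tlnP\n")
        with pytest.raises(SchemaError, match="FDR"):
            read_bedpe(p)

    def test_inverted_anchor_is_parse_error(self, tmp_path):
        p = tmp_path / "b.bedpe"
        p.write_text(self.HEADER + "chr1\t5000\t0\tchr1\t0\t5000\ti\t-10\t0\n")
        with pytest.raises(BedParseError):
            read_bedpe(p)

    def test_roundtrip(self, tmp_path):
        recs = [
            Interaction(iv("chr1", 0, 5000), iv("chr2", 10000, 15000), "a", -123.5, 0.0),
            Interaction(iv("chr3", 5000, 10000), iv("chr3", 0, 5000), "b", -7.25, 0.04),
        ]
        p = tmp_path / "rt.bedpe"
        write_bedpe(recs, p)
        assert read_bedpe(p) == recs

    def test_interaction_invariants(self):
        with pytest.raises(ValueError):
            Interaction(iv("chr1", 0, 10), iv("chr1", 20, 30), ln_p=1.0)
        with pytest.raises(ValueError):
            Interaction(iv("chr1", 0, 10), iv("chr1", 20, 30), fdr=-0.1)


class TestChromSizes:
    def test_read(self, tmp_path):
        p = tmp_path / "sizes.txt"
        p.write_text("chr1\t5000\nchr2\t3000\n")
        assert dict(read_chrom_sizes(p)) == {"chr1": 5000, "chr2": 3000}

    def test_duplicate_rejected(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("chr1\t5000\nchr1\t3000\n")
        with pytest.raises(BedParseError):
            read_chrom_sizes(p)


class TestArithmetic:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 100), ("chr1", 99, 200), True),  # 1-bp overlap
            (("chr1", 0, 100), ("chr1", 100, 200), False),  # half-open boundary
            (("chr1", 0, 100), ("chr2", 0, 100), False),  # different chromosome
        ],
    )
    def test_overlaps(self, a, b, expected):
        assert overlaps(iv(*a), iv(*b)) is expected

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 1000), ("chr1", 7000, 7001), 6000),
            (("chr1", 0, 100), ("chr1", 50, 200), 0),
            (("chr1", 0, 100), ("chr2", 0, 100), None),
        ],
    )
    def test_distance(self, a, b, expected):
        assert distance(iv(*a), iv(*b)) == expected

    intervals = st.builds(
        lambda c, s, w: iv(f"chr{c}", s, s + w),
        st.integers(1, 2),
        st.integers(0, 500),
        st.integers(1, 200),
    )

    @settings(max_examples=200, derandomize=True)
    @given(intervals, intervals)
    def test_symmetry_and_zero_distance_iff_contact(self, a, b):
        assert overlaps(a, b) == overlaps(b, a)
        assert distance(a, b) == distance(b, a)
        if a.chrom == b.chrom:
            touching = a.end == b.start or b.end == a.start
            assert (distance(a, b) == 0) == (overlaps(a, b) or touching)


class TestBinGenome:
    def test_examples(self):
        bins = bin_genome(GenomeTable({"c": 5000}), width=2000)
        assert [(b.start, b.end) for b in bins] == [(0, 2000), (2000, 4000), (4000, 5000)]
        assert [(b.start, b.end) for b in bin_genome(GenomeTable({"c": 2000}), 2000)] == [(0, 2000)]

    def test_partial_bin_flagged_by_length(self):
        bins = bin_genome(GenomeTable({"c": 4100}), width=2000)
        assert [b.length < 2000 for b in bins] == [False, False, True]

    @settings(max_examples=50, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["chr1", "chr2", "chr3"]), st.integers(1, 10_000), min_size=1
        ),
        st.integers(1, 3000),
    )
    def test_bins_tile_exactly(self, lengths, width):
        genome = GenomeTable(lengths)
        bins = bin_genome(genome, width=width)
        assert len(bins) == sum(-(-length // width) for length in lengths.values())
        for chrom, length in lengths.items():
            cb = [b for b in bins if b.chrom == chrom]
            assert cb[0].start == 0 and cb[-1].end == length
            assert sum(b.length for b in cb) == length
            for x, y in zip(cb, cb[1:]):
                assert x.end == y.start  # no gaps, no overlap
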