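"""Unit tests for I/O and binning."""

import numpy as np
import pytest

from depthcnv.depth import (BinTrack, bin_counts, load_genome_file,
                            load_methylation, load_reads, load_track,
                            read_segments, write_segments)
from depthcnv.segmentation import Segment


def write(path, text):
    path.write_text(text)
    return path


class TestLoadReads:
    def test_bed(self, tmp_path):
        bed = write(tmp_path / "r.bed",
                    "chr1\t10\t60\nchr1\t5\t55\nchr1\t100\t150\n")
        reads = load_reads(bed)
        assert list(reads["chr1"]) == [5, 10, 100]

    def test_undeclared_chrom_skipped_with_warning(self, tmp_path):
        bed = write(tmp_path / "r.bed", "chrUn\t10\t60\n")
        with pytest.warns(UserWarning, match="undeclared"):
            reads = load_reads(bed, chrom_lengths={"chr1": 1000})
        assert reads == {}

    def test_malformed_line_reports_number(self, tmp_path):
        bed = write(tmp_path / "r.bed", "chr1\t10\t60\nchr1\toops\n")
        with pytest.raises(ValueError, match="2"):
            load_reads(bed)

    def test_sam_drops_unmapped(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "chr1", "LN": 10_000}]}
        path = tmp_path / "r.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i in range(100):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read{i}"
                a.query_sequence = "ACGT" * 10
                a.reference_id = 0
                a.reference_start = 17 * i
                a.cigarstring = "40M"
                a.mapping_quality = 30
                out.write(a)
            for i in range(5):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"un{i}"
                a.query_sequence = "ACGT" * 10
                a.is_unmapped = True
                out.write(a)
        reads = load_reads(path, fmt="sam")
        assert len(reads["chr1"]) == 100


class TestBinCounts:
    def test_half_open_boundary(self):
        assert list(bin_counts([0, 999, 1000], 2000, 1000)) == [2, 1]

    def test_empty(self):
        assert list(bin_counts([], 2500, 1000)) == [0, 0, 0]

    def test_out_of_range_named(self):
        with pytest.raises(ValueError, match="2500"):
            bin_counts([10, 2500], 2000, 1000)

    def test_matches_histogram_oracle_and_conserves(self):
        rng = np.random.default_rng(3)
        L, b = 1_000_000, 1234
        pos = rng.integers(0, L, size=10 ** 5)
        counts = bin_counts(pos, L, b)
        edges = np.arange(0, L + b, b)
        oracle, _ = np.histogram(pos, bins=edges)
        assert np.array_equal(counts, oracle)
        assert counts.sum() == len(pos)


class TestLoadTrack:
    def test_constant_one(self, tmp_path):
        p = write(tmp_path / "t.bedGraph", "chr1\t0\t5000\t1.0\n")
        vals, cov = load_track(p, {"chr1": 5000}, 1000)
        assert np.allclose(vals["chr1"], 1.0)
        assert cov["chr1"].all()

    def test_length_weighting(self, tmp_path):
        p = write(tmp_path / "t.bedGraph", "chr1\t0\t500\t1.0\n")
        vals, cov = load_track(p, {"chr1": 1000}, 1000)
        assert vals["chr1"][0] == pytest.approx(0.5)

    def test_uncovered_bin_flagged(self, tmp_path):
        p = write(tmp_path / "t.bedGraph", "chr1\t0\t1000\t0.8\n")
        vals, cov = load_track(p, {"chr1": 3000}, 1000)
        assert not cov["chr1"][2]
        assert vals["chr1"][2] == 0.0

    def test_value_out_of_range(self, tmp_path):
        p = write(tmp_path / "t.bedGraph", "chr1\t0\t100\t1.5\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            load_track(p, {"chr1": 1000}, 100)

    def test_fixed_step_wiggle(self, tmp_path):
        p = write(tmp_path / "t.wig",
                  "fixedStep chrom=chr1 start=1 step=100 span=100\n"
                  "0.2\n0.4\n")
        vals, cov = load_track(p, {"chr1": 200}, 100)
        assert np.allclose(vals["chr1"], [0.2, 0.4])

    def test_matches_per_base_oracle(self, tmp_path):
        rng = np.random.default_rng(8)
        L, b = 10_000, 700
        edges = np.sort(rng.choice(np.arange(1, L), 20, replace=False))
        bounds = np.concatenate([[0], edges, [L]])
        vals = rng.uniform(0, 1, len(bounds) - 1)
        lines = [f"chr1\t{s}\t{e}\t{v:.10f}"
                 for s, e, v in zip(bounds[:-1], bounds[1:], vals)]
        p = write(tmp_path / "t.bedGraph", "\n".join(lines) + "\n")
        got, _ = load_track(p, {"chr1": L}, b)
        per_base = np.repeat(vals, np.diff(bounds))
        n_bins = -(-L // b)
        oracle = np.array([per_base[i * b:(i + 1) * b].mean()
                           for i in range(n_bins)])
        assert np.allclose(got["chr1"], oracle, atol=1e-12)


class TestMethylation:
    def test_two_rows(self, tmp_path):
        p = write(tmp_path / "m.tsv",
                  "chr1\t100\t+\t7\t10\nchr1\t200\t+\t0\t4\n")
        m = load_methylation(p)
        assert len(m) == 2

    def test_duplicate_position_rejected(self, tmp_path):
        p = write(tmp_path / "m.tsv",
                  "chr1\t100\t+\t7\t10\nchr1\t100\t-\t1\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_methylation(p)

    def test_meth_exceeding_total_rejected(self, tmp_path):
        p = write(tmp_path / "m.tsv", "chr1\t100\t+\t11\t10\n")
        with pytest.raises(ValueError, match="n_methylated"):
            load_methylation(p)

    def test_genomewide_fraction_recovered(self, tmp_path):
        # fixture constructed at an exact 0.7 genome-wide fraction
        rng = np.random.default_rng(5)
        totals = rng.integers(1, 20, 200) * 10
        meths = totals // 10 * 7
        lines = [f"chr1\t{i * 3}\t+\t{m}\t{t}"
                 for i, (m, t) in enumerate(zip(meths, totals))]
        p = write(tmp_path / "m.tsv", "\n".join(lines) + "\n")
        assert load_methylation(p).mean_fraction == pytest.approx(0.7)


class TestSegIO:
    @staticmethod
    def random_segments(rng, n=50):
        segs = []
        pos = 0
        for i in range(n):
            length = int(rng.integers(1, 50)) * 1000
            segs.append(Segment(
                chrom="chr1", start=pos, end=pos + length,
                n_bins=length // 1000,
                mean_depth=float(rng.uniform(10, 500)),
                copy_number=float(rng.uniform(0, 6)),
                call=str(rng.choice(["loss", "neutral", "gain"]))))
            pos += length
        return segs

    def test_single_segment(self, tmp_path):
        path = tmp_path / "o.seg"
        write_segments([Segment("chr1", 0, 1000, 1, 5.0, 2.0, "neutral")],
                       path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2 and lines[0].startswith("chrom")

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        segs = self.random_segments(rng)
        path = tmp_path / "o.seg"
        write_segments(segs, path)
        back = read_segments(path)
        assert len(back) == len(segs)
        for a, b in zip(segs, back):
            assert (a.chrom, a.start, a.end, a.n_bins, a.call) == \
                (b.chrom, b.start, b.end, b.n_bins, b.call)
            assert a.mean_depth == pytest.approx(b.mean_depth, abs=1e-6)

    def test_adjacent_segments_share_boundary(self, tmp_path):
        rng = np.random.default_rng(2)
        segs = self.random_segments(rng, n=5)
        path = tmp_path / "o.seg"
        write_segments(segs, path)
        back = read_segments(path)
        for a, b in zip(back[:-1], back[1:]):
            assert a.end == b.start

    def test_overlap_rejected(self, tmp_path):
        segs = [Segment("chr1", 0, 2000, 2, 5.0, 2.0, "neutral"),
                Segment("chr1", 1000, 3000, 2, 5.0, 2.0, "neutral")]
        with pytest.raises(ValueError, match="overlap"):
            write_segments(segs, tmp_path / "o.seg")


def test_genome_file(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("chr1\t1000\nchr2\t2000\n")
    assert load_genome_file(p) == {"chr1": 1000, "chr2": 2000}


def test_bintrack_validation():
    with pytest.raises(ValueError, match="bins"):
        BinTrack("chr1", 1000, 2500, np.zeros(2))
    t = BinTrack("chr1", 1000, 2500, np.zeros(3))
    assert t.partial_last and t.n_bins == 3
    assert t.bin_end(2) == 2500
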