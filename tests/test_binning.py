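"""Bin tiling, read counting, counts-table I/O and binomial downsampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasmacnv.binning import (
    BinProfile,
    count_reads,
    default_qc_mask,
    downsample_counts,
    make_binning,
    read_counts_table,
    write_counts_table,
)
from plasmacnv.errors import FormatError
from plasmacnv.genomes import HG19_SIZES


class TestMakeBinning:
    def test_short_last_bin(self):
        b = make_binning({"chr1": 50_000}, 20_000)
        assert list(zip(b.start, b.end)) == [(0, 20_000), (20_000, 40_000), (40_000, 50_000)]
        assert b.short_bin_mask.tolist() == [False, False, True]

    def test_exact_multiple_gives_one_bin(self):
        b = make_binning({"chr1": 20_000}, 20_000)
        assert b.n_bins == 1

    def test_hg19_bin_count_matches_ceil_sum_oracle(self):
        b = make_binning(HG19_SIZES, 20_000)
        # independent oracle: per-chromosome ceiling loop
        expected = 0
        for length in HG19_SIZES.values():
            n = 0
            pos = 0
            while pos < length:
                n += 1
                pos += 20_000
            assert n == math.ceil(length / 20_000)
            expected += n
        assert b.n_bins == expected

    def test_autosome_flags_and_chr_prefix_aliasing(self):
        b = make_binning({"1": 40_000, "chrX": 40_000, "22": 20_000}, 20_000)
        assert b.autosome_mask.tolist() == [True, True, False, False, True]
        assert b.chrom_slice("chr1") == b.chrom_slice("1")

    def test_duplicate_chromosome_rejected(self):
        with pytest.raises(FormatError):
            make_binning([("chr1", 100), ("1", 100)], 20)

    @pytest.mark.parametrize("sizes,width", [({"chr1": 0}, 20_000), ({"chr1": 100}, 0)])
    def test_non_positive_inputs_rejected(self, sizes, width):
        with pytest.raises(ValueError):
            make_binning(sizes, width)

    def test_mitochondrion_dropped_by_default(self):
        b = make_binning({"chr1": 40_000, "chrM": 16_000}, 20_000)
        assert b.chrom_names == ("chr1",)

    @given(
        lengths=st.lists(st.integers(1, 500_000), min_size=1, max_size=5),
        width=st.integers(1_000, 100_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_tiling_partitions_every_chromosome(self, lengths, width):
        sizes = {f"chr{i + 1}": n for i, n in enumerate(lengths)}
        b = make_binning(sizes, width)
        widths = b.end - b.start
        assert np.all(widths > 0) and np.all(widths <= width)
        for i, (name, length) in enumerate(sizes.items()):
            sl = b.chrom_slice(name)
            assert b.start[sl][0] == 0
            assert b.end[sl][-1] == length
            # contiguous: each bin starts where the previous ended
            assert np.array_equal(b.start[sl][1:], b.end[sl][:-1])


def _write_sam(path, binning, positions, mapq=60):
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": n, "LN": int(l)}
            for n, l in zip(binning.chrom_names, binning.chrom_lengths)
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (chrom, pos) in enumerate(positions):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.query_sequence = "A" * 35
            a.reference_id = binning.chrom_names.index(chrom)
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = "35M"
            a.flag = 0
            out.write(a)


class TestCountReads:
    def test_empty_alignment_gives_zero_profile(self, tmp_path):
        b = make_binning({"chr1": 40_000}, 20_000)
        sam = tmp_path / "empty.sam"
        _write_sam(sam, b, [])
        p = count_reads(sam, b)
        assert p.total_umr == 0 and p.values.sum() == 0

    def test_half_open_bin_boundaries(self, tmp_path):
        b = make_binning({"chr1": 40_000}, 20_000)
        sam = tmp_path / "three.sam"
        _write_sam(sam, b, [("chr1", 0), ("chr1", 19_999), ("chr1", 20_000)])
        p = count_reads(sam, b)
        assert p.values.tolist() == [2, 1]
        assert p.total_umr == 3

    def test_low_mapq_and_unknown_chrom_excluded(self, tmp_path):
        import pysam

        b = make_binning({"chr1": 40_000}, 20_000)
        sam = tmp_path / "mixed.sam"
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chr1", "LN": 40_000}, {"SN": "chrUn_gl000220", "LN": 40_000}],
        }
        with pysam.AlignmentFile(str(sam), "w", header=header) as out:
            for name, rid, pos, mapq in [("a", 0, 5, 60), ("b", 0, 6, 5), ("c", 1, 7, 60)]:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.query_sequence = "A" * 35
                a.reference_id = rid
                a.reference_start = pos
                a.mapping_quality = mapq
                a.cigarstring = "35M"
                out.write(a)
        p = count_reads(sam, b, min_mapq=20)
        assert p.total_umr == 1 and p.values.tolist() == [1, 0]

    def test_counts_match_simulated_multinomial_draw(self, tmp_path):
        rng = np.random.default_rng(5)
        b = make_binning({"chr1": 100_000, "chr2": 60_000}, 20_000)
        truth = rng.multinomial(300, np.ones(b.n_bins) / b.n_bins)
        positions = []
        for i, c in enumerate(truth):
            chrom = b.chrom_names[b.bin_chrom[i]]
            for _ in range(c):
                positions.append((chrom, int(rng.integers(b.start[i], b.end[i]))))
        positions.sort(key=lambda t: (t[0], t[1]))
        sam = tmp_path / "sim.sam"
        _write_sam(sam, b, positions)
        p = count_reads(sam, b)
        assert p.values.tolist() == truth.tolist()


class TestCountsTable:
    def test_round_trip_identity(self, tmp_path, toy_genome_shared):
        b = toy_genome_shared.binning
        rng = np.random.default_rng(0)
        vals = rng.poisson(100, b.n_bins)
        prof = BinProfile(b, vals, default_qc_mask(b), int(vals.sum()))
        f = tmp_path / "c.tsv"
        write_counts_table(prof, f)
        back = read_counts_table(f, b)
        assert np.array_equal(back.values, prof.values)
        assert back.total_umr == vals.sum()

    def test_header_and_headerless_dialects_agree(self, tmp_path):
        b = make_binning({"chr1": 60_000}, 20_000)
        prof = BinProfile(b, [5, 7, 9], default_qc_mask(b), 21)
        with_h = tmp_path / "h.tsv"
        without_h = tmp_path / "bed.tsv"
        write_counts_table(prof, with_h, header=True)
        write_counts_table(prof, without_h, header=False)
        assert len(with_h.read_text().splitlines()) == 4  # header + 3 rows
        a = read_counts_table(with_h, b)
        c = read_counts_table(without_h, b)
        assert np.array_equal(a.values, c.values)

    def test_row_count_mismatch_rejected(self, tmp_path):
        b = make_binning({"chr1": 60_000}, 20_000)
        f = tmp_path / "bad.tsv"
        f.write_text("chr1\t0\t20000\t5\n")
        with pytest.raises(FormatError):
            read_counts_table(f, b)

    def test_negative_count_rejected(self, tmp_path):
        b = make_binning({"chr1": 40_000}, 20_000)
        f = tmp_path / "neg.tsv"
        f.write_text("chr1\t0\t20000\t5\nchr1\t20000\t40000\t-1\n")
        with pytest.raises(ValueError):
            read_counts_table(f, b)


class TestDownsample:
    def _profile(self, counts):
        counts = np.asarray(counts)
        b = make_binning({"chr1": 20_000 * counts.size}, 20_000)
        return BinProfile(b, counts, default_qc_mask(b), int(counts.sum()))

    def test_ratio_one_is_identity(self):
        p = self._profile([10, 20, 30])
        q = downsample_counts(p, p.total_umr, seed=1)
        assert np.array_equal(q.values, p.values)

    def test_upsampling_rejected(self):
        p = self._profile([10])
        with pytest.raises(ValueError):
            downsample_counts(p, 11, seed=1)

    def test_binomial_moments_at_half(self):
        p = self._profile([1000])
        reps = np.array(
            [downsample_counts(p, 500, seed=s).values[0] for s in range(2000)]
        )
        se = math.sqrt(1000 * 0.5 * 0.5 / reps.size)
        assert abs(reps.mean() - 500) < 3 * se

    def test_realized_total_near_target(self):
        # thinning a deep profile down to a target: realized total within 5 SD
        rng = np.random.default_rng(3)
        counts = rng.poisson(200, 1000)
        p = self._profile(counts)
        target = int(p.total_umr * 20 / 31.68)
        q = downsample_counts(p, target, seed=9)
        ratio = target / p.total_umr
        sd = math.sqrt(p.total_umr * ratio * (1 - ratio))
        assert abs(q.values.sum() - target) < 5 * sd
        assert q.total_umr == q.values.sum()

    def test_two_step_thinning_matches_single_step_moments(self):
        # thinning by r1 then r2 ~ thinning by r1*r2 (means over seeded reps)
        p = self._profile([2000])
        two_step = []
        one_step = []
        for s in range(500):
            a = downsample_counts(p, 1000, seed=s)
            two_step.append(downsample_counts(a, int(a.total_umr * 0.6), seed=s + 7).values[0])
            one_step.append(downsample_counts(p, 600, seed=s + 13).values[0])
        two_step, one_step = np.array(two_step), np.array(one_step)
        pooled_se = math.sqrt(two_step.var() / 500 + one_step.var() / 500)
        assert abs(two_step.mean() - one_step.mean()) < 4 * pooled_se
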