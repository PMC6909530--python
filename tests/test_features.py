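"""Feature extraction: insert statistics, pair classification, position tracks."""

import numpy as np
import pytest

import delcall as dc
from delcall.features import DISCORDANCE_SDS
from delcall.records import AlignedRead


def mk_read(name, start, cigar, tlen=0, mapq=60, paired=True, supp=False,
            chrom="chr1", mate_start=-1, seq=None):
    qlen = sum(n for op, n in cigar if op in "MIS=X")
    return AlignedRead(name=name, chrom=chrom, start=start, mapq=mapq,
                       cigar=cigar, seq=seq or "A" * qlen, is_paired=paired,
                       is_supplementary=supp, mate_start=mate_start, tlen=tlen)


class TestInsertStats:
    def test_recovers_simulated_library(self, homo_scene, homo_stats):
        assert abs(homo_stats.mean - 456) <= 5
        assert abs(homo_stats.sd - 60) <= 8

    def test_degenerate_spread_hits_floor(self):
        reads = [mk_read(f"r{i}", i * 10, [("M", 100)], tlen=456)
                 for i in range(200)]
        st = dc.estimate_insert_stats(reads)
        assert st.mean == 456 and st.sd == pytest.approx(1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="100"):
            dc.estimate_insert_stats([])

    def test_robust_to_discordant_tail(self):
        # a 10% tail of deletion-inflated inserts should barely move the stats
        rng = np.random.default_rng(0)
        tlens = np.concatenate([rng.normal(456, 60, 900),
                                rng.normal(2456, 60, 100)])
        reads = [mk_read(f"r{i}", i, [("M", 100)], tlen=int(t))
                 for i, t in enumerate(tlens)]
        st = dc.estimate_insert_stats(reads)
        assert abs(st.mean - 456) <= 15 and abs(st.sd - 60) <= 15


class TestClassifyPair:
    @pytest.mark.parametrize("insert,expected", [
        (456, "concordant"),   # zero deviation
        (640, "discordant"),   # 184 >= 3*60
        (635, "concordant"),   # 179 < 180
        (276, "discordant"),   # symmetric on the short side
    ])
    def test_three_sigma_rule(self, insert, expected):
        st = dc.InsertStats(mean=456, sd=60)
        assert dc.classify_pair(insert, st) == expected

    def test_negative_insert_rejected(self):
        with pytest.raises(ValueError):
            dc.classify_pair(-1, dc.InsertStats(456, 60))


class TestIsSplitRead:
    @pytest.mark.parametrize("cigar,expected", [
        ([("M", 100)], False),
        ([("M", 60), ("S", 40)], True),
        ([("M", 95), ("S", 5)], False),   # below the 10 bp clip threshold
        ([("S", 10), ("M", 90)], True),
    ])
    def test_clip_threshold(self, cigar, expected):
        assert dc.is_split_read(mk_read("r", 100, cigar)) is expected

    def test_supplementary_counts_as_split(self):
        assert dc.is_split_read(mk_read("r", 100, [("M", 100)], supp=True))

    def test_missing_cigar_rejected(self):
        r = mk_read("r", 100, [("M", 100)])
        r.cigar = []
        with pytest.raises(ValueError):
            dc.is_split_read(r)


def brute_force_features(reads, chrom, start, end, stats, min_clip=10):
    """Independent per-record x per-position enumeration of the three tracks."""
    n = end - start
    depth = np.zeros(n, int)
    split = np.zeros(n, int)
    disc = np.zeros(n, int)
    for r in reads:
        if r.chrom != chrom or r.is_secondary or r.is_duplicate:
            continue
        if r.is_primary:
            for pos in range(start, end):
                if any(b0 <= pos < b1 for b0, b1 in r.aligned_blocks()):
                    depth[pos - start] += 1
        if dc.is_split_read(r, min_clip=min_clip):
            lead, trail = r.clip_lengths
            clip_points = []
            if lead >= min_clip:
                clip_points.append(r.start)
            if trail >= min_clip:
                clip_points.append(r.reference_end)
            for pos in clip_points:
                if start <= pos < end:
                    split[pos - start] += 1
        if (r.is_primary and r.is_paired and r.tlen > 0
                and abs(r.tlen - stats.mean) >= DISCORDANCE_SDS * stats.sd):
            for pos in range(start, end):
                if r.start <= pos < r.start + r.tlen:
                    disc[pos - start] += 1
    return depth, split, disc


class TestPositionFeatures:
    def test_empty_region_all_zero(self):
        st = dc.InsertStats(456, 60)
        tr = dc.position_features([], "chr1", 100, 200, stats=st)
        assert not tr.depth.any() and not tr.split.any() and not tr.discordant.any()

    def test_three_reads_over_one_position(self):
        st = dc.InsertStats(456, 60)
        reads = [mk_read(f"r{i}", 100, [("M", 100)]) for i in range(3)]
        tr = dc.position_features(reads, "chr1", 150, 151, stats=st)
        assert tr.depth[0] == 3

    def test_matches_brute_force_oracle(self):
        # hand-placed toy: 8 plain reads, 2 split records, 1 discordant pair
        st = dc.InsertStats(456, 60)
        reads = [
            mk_read("a", 100, [("M", 100)], tlen=450),
            mk_read("b", 150, [("M", 100)], tlen=460),
            mk_read("c", 180, [("M", 100)], tlen=440),
            mk_read("d", 260, [("M", 100)], tlen=-450),
            mk_read("e", 300, [("M", 100)], tlen=470),
            mk_read("f", 380, [("M", 100)], tlen=-460),
            mk_read("g", 420, [("M", 100)], tlen=455),
            mk_read("h", 500, [("M", 100)], tlen=-440),
            mk_read("s1", 200, [("M", 60), ("S", 40)], tlen=450),
            mk_read("s1", 700, [("S", 60), ("M", 40)], tlen=450, supp=True),
            mk_read("p1", 240, [("M", 100)], tlen=900),       # discordant left
            mk_read("p2", 1040, [("M", 100)], tlen=-900),     # discordant right
        ]
        reads.sort(key=lambda r: r.start)
        tr = dc.position_features(reads, "chr1", 0, 1200, stats=st)
        depth, split, disc = brute_force_features(reads, "chr1", 0, 1200, st)
        np.testing.assert_array_equal(tr.depth, depth)
        np.testing.assert_array_equal(tr.split, split)
        np.testing.assert_array_equal(tr.discordant, disc)

    def test_depth_sum_equals_aligned_bases(self, homo_scene, homo_stats):
        lo, hi = 10_000, 20_000
        tr = dc.position_features(homo_scene.reads, "chr1", lo, hi,
                                  stats=homo_stats, check_sorted=False)
        expected = sum(min(b1, hi) - max(b0, lo)
                       for r in homo_scene.reads if r.is_primary
                       for b0, b1 in r.aligned_blocks()
                       if b0 < hi and b1 > lo)
        assert tr.depth.sum() == expected

    def test_unsorted_input_rejected(self):
        st = dc.InsertStats(456, 60)
        reads = [mk_read("a", 500, [("M", 100)]), mk_read("b", 100, [("M", 100)])]
        with pytest.raises(ValueError, match="sorted"):
            dc.position_features(reads, "chr1", 0, 1000, stats=st)

    def test_signature_localisation_around_deletion(self, homo_scene, homo_stats):
        d = homo_scene.deletions[0]
        lib = homo_scene.lib
        tr = dc.position_features(homo_scene.reads, "chr1", 0, homo_scene.length,
                                  stats=homo_stats, check_sorted=False)
        # discordant support confined to the deletion +- one insert
        reach = int(lib.insert_mean + 4 * lib.insert_sd)
        outside = np.r_[tr.discordant[:d.start - reach - d.length],
                        tr.discordant[d.end + reach + d.length:]]
        assert outside.max() <= 2
        # split spikes within a read length of each true breakpoint
        for bp in (d.start, d.end):
            lo, hi = bp - lib.read_length, bp + lib.read_length
            assert tr.split[lo:hi].max() >= 5
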