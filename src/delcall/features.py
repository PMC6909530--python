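"""Per-position deletion signatures from mapped reads.

Three tracks are extracted over a region: read depth (aligned bases of primary
records), split-read count (records clipped at least ``min_clip`` bases or
flagged supplementary, spread over their aligned span) and discordant-pair
count (pairs whose observed insert deviates from the library mean by at least
three standard deviations, spread over the pair's outer span so that the
interior of an encompassed deletion receives support).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .records import AlignedRead

DEFAULT_MIN_CLIP = 10
DISCORDANCE_SDS = 3.0
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class InsertStats:
    """Robust library insert-size statistics."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("insert sd must be positive")


@dataclass(frozen=True)
class PositionFeature:
    chrom: str
    position: int
    depth: int
    split_count: int
    discordant_count: int


def estimate_insert_stats(reads: Sequence[AlignedRead], sample_size: int = 10000,
                          sd_floor: float = 1e-6) -> InsertStats:
    """Median / scaled-MAD insert statistics over sampled proper pairs.

    Robust to the inflated inserts of deletion-encompassing pairs, which would
    bias a plain mean/sd upward.
    """
    tlens = np.array([r.tlen for r in reads
                      if r.is_paired and r.is_primary and r.tlen > 0],
                     dtype=np.float64)
    if tlens.size < 100:
        raise ValueError(f"need >= 100 proper pairs to estimate insert size, "
                         f"got {tlens.size}")
    if tlens.size > sample_size:
        idx = np.linspace(0, tlens.size - 1, sample_size).astype(np.int64)
        tlens = tlens[idx]
    med = float(np.median(tlens))
    mad = float(np.median(np.abs(tlens - med)))
    return InsertStats(mean=med, sd=max(MAD_TO_SD * mad, sd_floor))


def classify_pair(observed_insert: float, stats: InsertStats) -> str:
    """'discordant' iff |insert - mean| >= 3 sd, else 'concordant'."""
    if observed_insert < 0:
        raise ValueError("observed insert must be non-negative")
    dev = abs(observed_insert - stats.mean)
    return "discordant" if dev >= DISCORDANCE_SDS * stats.sd else "concordant"


def is_split_read(read: AlignedRead, min_clip: int = DEFAULT_MIN_CLIP) -> bool:
    """A record is split if supplementary or clipped >= min_clip bases."""
    if not read.cigar:
        raise ValueError(f"record {read.name} has no parseable CIGAR")
    if read.is_supplementary:
        return True
    lead, trail = read.clip_lengths
    return max(lead, trail) >= min_clip


@dataclass
class FeatureTrack:
    """Signature tracks over a half-open region [start, end) of one chromosome."""

    chrom: str
    start: int
    depth: np.ndarray
    split: np.ndarray
    discordant: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.depth)

    def __len__(self) -> int:
        return len(self.depth)

    def __iter__(self) -> Iterator[PositionFeature]:
        for i in range(len(self.depth)):
            yield PositionFeature(self.chrom, self.start + i, int(self.depth[i]),
                                  int(self.split[i]), int(self.discordant[i]))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "chrom": self.chrom,
            "pos": np.arange(self.start, self.end),
            "depth": self.depth, "split": self.split, "discordant": self.discordant,
        })


def _check_sorted(reads: Sequence[AlignedRead]) -> None:
    prev = None
    for r in reads:
        key = (r.chrom, r.start)
        if prev is not None and key < prev:
            raise ValueError("alignments must be coordinate-sorted")
        prev = key


def position_features(reads: Sequence[AlignedRead], chrom: str, start: int,
                      end: int, stats: InsertStats | None = None,
                      min_clip: int = DEFAULT_MIN_CLIP,
                      split_mode: str = "clip",
                      check_sorted: bool = True) -> FeatureTrack:
    """Compute (depth, split, discordant) counts per reference position.

    Depth counts aligned bases of primary, non-duplicate records only.
    Discordant support is spread over the leftmost mate's outer span and
    counted once per pair, so the interior of an encompassed deletion receives
    signal.  Split support is assigned at each qualifying clip point
    (``split_mode="clip"``, the default), concentrating it exactly on the
    breakpoints; ``split_mode="span"`` spreads it over the record's aligned
    span instead, which smears breakpoint evidence across the flanks.
    """
    if split_mode not in ("clip", "span"):
        raise ValueError(f"unknown split_mode {split_mode!r}")
    if end <= start:
        raise ValueError("empty region")
    if check_sorted:
        _check_sorted(reads)
    if stats is None:
        stats = estimate_insert_stats(reads)
    n = end - start
    d_depth = np.zeros(n + 1, dtype=np.int64)
    d_split = np.zeros(n + 1, dtype=np.int64)
    d_disc = np.zeros(n + 1, dtype=np.int64)
    cutoff = DISCORDANCE_SDS * stats.sd

    def add(diff, lo, hi):
        lo, hi = max(lo, start), min(hi, end)
        if lo < hi:
            diff[lo - start] += 1
            diff[hi - start] -= 1

    for r in reads:
        if r.chrom != chrom or r.is_secondary or r.is_duplicate:
            continue
        if r.is_primary:
            for b0, b1 in r.aligned_blocks():
                add(d_depth, b0, b1)
        if is_split_read(r, min_clip=min_clip):
            if split_mode == "span":
                add(d_split, r.start, r.reference_end)
            else:
                lead, trail = r.clip_lengths
                if lead >= min_clip:
                    add(d_split, r.start, r.start + 1)
                if trail >= min_clip:
                    add(d_split, r.reference_end, r.reference_end + 1)
        if (r.is_primary and r.is_paired and r.tlen > 0
                and abs(r.tlen - stats.mean) >= cutoff):
            add(d_disc, r.start, r.start + r.tlen)

    return FeatureTrack(chrom, start,
                        np.cumsum(d_depth[:-1]),
                        np.cumsum(d_split[:-1]),
                        np.cumsum(d_disc[:-1]))


class ReadIndex:
    """Sorted-start index for fast region queries over one chromosome."""

    def __init__(self, reads: Sequence[AlignedRead], max_span: int | None = None):
        self.reads = sorted(reads, key=lambda r: (r.chrom, r.start))
        self.starts = np.array([r.start for r in self.reads], dtype=np.int64)
        if max_span is None:
            max_span = max((r.reference_end - r.start for r in self.reads), default=0)
        self.max_span = max_span
        # longest pair outer span: how far left a pair can start and still
        # cover a position with its discordant-support interval
        self.max_outer_span = max((r.tlen for r in self.reads if r.tlen > 0),
                                  default=max_span)

    def overlapping(self, start: int, end: int) -> list[AlignedRead]:
        lo = int(np.searchsorted(self.starts, start - self.max_span, side="left"))
        hi = int(np.searchsorted(self.starts, end, side="left"))
        return [r for r in self.reads[lo:hi] if r.reference_end > start]
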