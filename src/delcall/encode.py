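"""Pileup-to-image encoding of 50 bp windows.

Each reference window becomes a 256x256 RGB image on a white background.  A
window column (one reference position) is a vertical bar of pixels, one per
aligned base, stacked bottom-up in deterministic read order, so bar height
encodes read depth.  Base identity picks the dominant channel(s):

    A -> (255, 0, 0)   T -> (0, 255, 0)   C -> (0, 0, 255)   G -> (0, 0, 0)

and the deletion signatures tint the auxiliary channels: the column's
discordant-pair and split-read counts set a column-wide auxiliary level, and
each base adds its own per-base value — the column discordant count plus four
binary feature bits (is-paired, is-discordant, mapping quality > 20,
is-split).  Auxiliary channels are clamped to 235 so every colour stays inside
the per-base range, e.g. A spans (255,0,0) ~ (255,235,235).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import InsertStats, is_split_read, DISCORDANCE_SDS, DEFAULT_MIN_CLIP

log = logging.getLogger(__name__)

WINDOW_BP = 50
IMAGE_SIZE = 256
COLUMN_WIDTH = 5        # 50 columns x 5 px = 250 px, 3 px margins
MARGIN = 3
AUX_MAX = 235
DEPTH_SCALE = 200       # deepest pixel row used per column
MAPQ_THRESHOLD = 20

BASE_CHANNELS = {"A": (0,), "T": (1,), "C": (2,), "G": ()}
WHITE = (255, 255, 255)


@dataclass(frozen=True)
class BaseFeatureBits:
    """Binary per-base features describing the carrying read."""

    is_paired: int = 0
    is_discordant: int = 0
    mapq_high: int = 0
    is_split: int = 0

    def __post_init__(self):
        for v in (self.is_paired, self.is_discordant, self.mapq_high, self.is_split):
            if v not in (0, 1):
                raise ValueError("feature bits must be 0 or 1")

    @property
    def total(self) -> int:
        return self.is_paired + self.is_discordant + self.mapq_high + self.is_split

    @property
    def binary(self) -> int:
        """The bits read as a 4-bit binary number (injective over combinations)."""
        return (self.is_paired << 3 | self.is_discordant << 2
                | self.mapq_high << 1 | self.is_split)


@dataclass
class PileupColumn:
    """All aligned bases at one reference position."""

    position: int
    bases: list[tuple[str, BaseFeatureBits]] = field(default_factory=list)
    n_discordant: int = 0
    n_split: int = 0

    @property
    def depth(self) -> int:
        return len(self.bases)


def base_color(base: str) -> tuple[int, int, int]:
    """Pure base colour; unknown symbols map to the white sentinel."""
    colors = {"A": (255, 0, 0), "T": (0, 255, 0), "C": (0, 0, 255), "G": (0, 0, 0)}
    if base not in colors:
        log.debug("non-ACGT base %r rendered as background", base)
        return WHITE
    return colors[base]


def _with_aux(base: str, aux: int) -> tuple[int, int, int]:
    aux = int(min(max(aux, 0), AUX_MAX))
    if base not in BASE_CHANNELS:
        return WHITE
    dominant = BASE_CHANNELS[base]
    color = [aux, aux, aux]
    for ch in dominant:
        color[ch] = 255
    return tuple(color)


def column_base_color(base: str, n_discordant: int, n_split: int) -> tuple[int, int, int]:
    """Column-wide colour: auxiliary channels carry the signature counts."""
    if n_discordant < 0 or n_split < 0:
        raise ValueError("counts must be non-negative")
    return _with_aux(base, n_discordant + n_split)


def base_aux_value(n_discordant: int, bits: BaseFeatureBits) -> int:
    """Per-base auxiliary value: column discordant count plus the feature bits."""
    if n_discordant < 0:
        raise ValueError("count must be non-negative")
    return n_discordant + bits.total


def rendered_base_color(base: str, n_discordant: int, n_split: int,
                        bits: BaseFeatureBits) -> tuple[int, int, int]:
    """Final pixel colour: column colour plus the per-base auxiliary values.

    The first auxiliary channel carries the per-base sum (column discordant
    count plus the four feature bits); the second carries the bits read as a
    4-bit binary number, so all 64 (base, bits) combinations map to distinct
    colours.  Both channels clamp at 235, keeping every colour inside the
    per-base range (A: (255,0,0) ~ (255,235,235), analogously for T/C/G).
    """
    column_aux = min(max(n_discordant + n_split, 0), AUX_MAX)
    aux_sum = min(column_aux + base_aux_value(n_discordant, bits), AUX_MAX)
    aux_bin = min(column_aux + n_discordant + bits.binary, AUX_MAX)
    if base == "A":
        return (255, aux_sum, aux_bin)
    if base == "T":
        return (aux_sum, 255, aux_bin)
    if base == "C":
        return (aux_sum, aux_bin, 255)
    if base == "G":
        return (aux_sum, aux_bin, aux_sum)
    return WHITE


def feature_table() -> list[tuple[str, BaseFeatureBits, tuple[int, int, int]]]:
    """Enumerate all 4 x 16 (base, bits) combinations at zero column counts."""
    rows = []
    for base in "ATCG":
        for code in range(16):
            bits = BaseFeatureBits((code >> 3) & 1, (code >> 2) & 1,
                                   (code >> 1) & 1, code & 1)
            rows.append((base, bits, rendered_base_color(base, 0, 0, bits)))
    return rows


@dataclass
class WindowImage:
    pixels: np.ndarray            # (256, 256, 3) uint8
    label: int
    chrom: str
    start: int

    @property
    def end(self) -> int:
        return self.start + WINDOW_BP


def pileup_columns(reads, chrom: str, start: int, stats: InsertStats,
                   min_clip: int = DEFAULT_MIN_CLIP) -> list[PileupColumn]:
    """Build the 50 pileup columns of window [start, start+50).

    ``reads`` are the alignments overlapping the window (primary and
    supplementary records both contribute their aligned bases).  Reads are
    stacked in (mapped start, name) order so rendering is deterministic.
    """
    end = start + WINDOW_BP
    cols = [PileupColumn(position=start + i) for i in range(WINDOW_BP)]
    cutoff = DISCORDANCE_SDS * stats.sd
    seen_disc_pairs: set[str] = set()
    for r in sorted(reads, key=lambda r: (r.start, r.name, r.is_supplementary)):
        if r.chrom != chrom or r.is_secondary or r.is_duplicate:
            continue
        discordant = bool(r.is_paired and abs(abs(r.tlen) - stats.mean) >= cutoff)
        split = is_split_read(r, min_clip=min_clip)
        bits = BaseFeatureBits(int(r.is_paired), int(discordant),
                               int(r.mapq > MAPQ_THRESHOLD), int(split))
        # per-base stacking over the aligned span, tracking query offsets
        qoff = 0
        ref = r.start
        for op, n in r.cigar:
            if op in "M=X":
                lo = max(ref, start)
                hi = min(ref + n, end)
                for pos in range(lo, hi):
                    b = r.seq[qoff + (pos - ref)] if r.seq else "N"
                    cols[pos - start].bases.append((b, bits))
                ref += n
                qoff += n
            elif op in "DN":
                ref += n
            elif op in "SI":
                qoff += n
        # column-level signature counts
        if split:
            lo, hi = max(r.start, start), min(r.reference_end, end)
            for pos in range(lo, hi):
                cols[pos - start].n_split += 1
        if discordant and r.is_primary and r.tlen > 0 and r.name not in seen_disc_pairs:
            seen_disc_pairs.add(r.name)
            lo, hi = max(r.start, start), min(r.start + r.tlen, end)
            for pos in range(lo, hi):
                cols[pos - start].n_discordant += 1
    return cols


def render_window(columns: Sequence[PileupColumn], depth_scale: int = DEPTH_SCALE,
                  label: int = 0, chrom: str = "chr1", start: int | None = None
                  ) -> WindowImage:
    """Render 50 pileup columns onto a white 256x256 RGB canvas."""
    if len(columns) != WINDOW_BP:
        raise ValueError(f"expected exactly {WINDOW_BP} columns, got {len(columns)}")
    canvas = np.full((IMAGE_SIZE, IMAGE_SIZE, 3), 255, dtype=np.uint8)
    for i, col in enumerate(columns):
        x0 = MARGIN + i * COLUMN_WIDTH
        for row, (b, bits) in enumerate(col.bases[:depth_scale]):
            color = rendered_base_color(b, col.n_discordant, col.n_split, bits)
            y = IMAGE_SIZE - 1 - row
            canvas[y, x0:x0 + COLUMN_WIDTH] = color
    if start is None:
        start = columns[0].position if columns else 0
    return WindowImage(pixels=canvas, label=label, chrom=chrom, start=start)


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ATCG"):
    _BASE_CODE[_b] = _i


def _pixel_colors(codes: np.ndarray, col_aux: np.ndarray, n_disc: np.ndarray,
                  bits_total, bits_binary) -> np.ndarray:
    """Vectorized ``rendered_base_color``: (m, 3) uint8 for coded bases."""
    aux_sum = np.clip(col_aux + n_disc + bits_total, 0, AUX_MAX).astype(np.uint8)
    aux_bin = np.clip(col_aux + n_disc + bits_binary, 0, AUX_MAX).astype(np.uint8)
    ch0 = np.where(codes == 0, 255, aux_sum)
    ch1 = np.where(codes == 1, 255, np.where(codes == 0, aux_sum, aux_bin))
    ch2 = np.where(codes == 2, 255, np.where(codes == 3, aux_sum, aux_bin))
    colors = np.stack([ch0, ch1, ch2], axis=1).astype(np.uint8)
    colors[codes < 0] = 255
    return colors


def render_window_fast(reads, chrom: str, start: int, stats: InsertStats,
                       min_clip: int = DEFAULT_MIN_CLIP,
                       depth_scale: int = DEPTH_SCALE) -> np.ndarray:
    """Vectorized equivalent of ``pileup_columns`` + ``render_window``.

    Returns the (256, 256, 3) uint8 pixel grid directly; byte-identical to the
    column-based path (asserted in the test suite) but an order of magnitude
    faster, which matters when classifying a whole chromosome.
    """
    end = start + WINDOW_BP
    cutoff = DISCORDANCE_SDS * stats.sd
    n_disc = np.zeros(WINDOW_BP, dtype=np.int64)
    n_split = np.zeros(WINDOW_BP, dtype=np.int64)
    entries = []   # (read order key, c0, c1, base codes, bits_total, dominant mask rows)
    seen_disc: set[str] = set()
    ordered = sorted(reads, key=lambda r: (r.start, r.name, r.is_supplementary))
    for r in ordered:
        if r.chrom != chrom or r.is_secondary or r.is_duplicate:
            continue
        discordant = bool(r.is_paired and abs(abs(r.tlen) - stats.mean) >= cutoff)
        split = is_split_read(r, min_clip=min_clip)
        bits_total = (int(r.is_paired) + int(discordant)
                      + int(r.mapq > MAPQ_THRESHOLD) + int(split))
        bits_binary = (int(r.is_paired) << 3 | int(discordant) << 2
                       | int(r.mapq > MAPQ_THRESHOLD) << 1 | int(split))
        if split:
            lo, hi = max(r.start, start), min(r.reference_end, end)
            if lo < hi:
                n_split[lo - start:hi - start] += 1
        if discordant and r.is_primary and r.tlen > 0 and r.name not in seen_disc:
            seen_disc.add(r.name)
            lo, hi = max(r.start, start), min(r.start + r.tlen, end)
            if lo < hi:
                n_disc[lo - start:hi - start] += 1
        qoff, ref = 0, r.start
        for op, n in r.cigar:
            if op in "M=X":
                lo, hi = max(ref, start), min(ref + n, end)
                if lo < hi:
                    codes = _BASE_CODE[np.frombuffer(
                        r.seq[qoff + lo - ref: qoff + hi - ref].encode("ascii"),
                        dtype=np.uint8)]
                    entries.append((lo - start, hi - start, codes,
                                    bits_total, bits_binary))
                ref += n
                qoff += n
            elif op in "DN":
                ref += n
            elif op in "SI":
                qoff += n

    canvas = np.full((IMAGE_SIZE, IMAGE_SIZE, 3), 255, dtype=np.uint8)
    rank = np.zeros(WINDOW_BP, dtype=np.int64)
    col_aux = np.clip(n_disc + n_split, 0, AUX_MAX)
    x_block = np.arange(COLUMN_WIDTH)
    for c0, c1, codes, bits_total, bits_binary in entries:
        cols = np.arange(c0, c1)
        rows = rank[cols].copy()
        rank[cols] += 1
        keep = (rows < depth_scale) & (codes >= 0)
        if not keep.any():
            continue
        cols, rows, kcodes = cols[keep], rows[keep], codes[keep]
        colors = _pixel_colors(kcodes, col_aux[cols], n_disc[cols],
                               bits_total, bits_binary)
        y = IMAGE_SIZE - 1 - rows
        x = MARGIN + cols * COLUMN_WIDTH
        canvas[y[:, None], x[:, None] + x_block] = colors[:, None, :]
        # unknown bases render white: paint them explicitly (sentinel)
        bad = codes < 0
        if bad.any():
            cols_b = np.arange(c0, c1)[bad]
            rows_b = (rank[cols_b] - 1)
            ok = rows_b < depth_scale
            if ok.any():
                yb = IMAGE_SIZE - 1 - rows_b[ok]
                xb = MARGIN + cols_b[ok] * COLUMN_WIDTH
                canvas[yb[:, None], xb[:, None] + x_block] = 255
    return canvas


def render_batch(reads, chrom: str, starts: np.ndarray, stats: InsertStats,
                 min_clip: int = DEFAULT_MIN_CLIP,
                 depth_scale: int = DEPTH_SCALE) -> np.ndarray:
    """Render many windows at once; byte-identical to ``render_window_fast``.

    ``starts`` must be sorted, non-overlapping 50 bp window starts.  ``reads``
    should include every record whose alignment or pair outer span can touch a
    window, so the column discordant counts are complete.  Returns an
    (n, 256, 256, 3) uint8 stack.
    """
    starts = np.asarray(starts, dtype=np.int64)
    n_win = len(starts)
    canvas = np.full((n_win, IMAGE_SIZE, IMAGE_SIZE, 3), 255, dtype=np.uint8)
    if n_win == 0:
        return canvas
    lo, hi = int(starts[0]), int(starts[-1]) + WINDOW_BP
    span = hi - lo
    d_disc = np.zeros(span + 1, dtype=np.int32)
    d_split = np.zeros(span + 1, dtype=np.int32)
    cutoff = DISCORDANCE_SDS * stats.sd
    rank = np.zeros((n_win, WINDOW_BP), dtype=np.int32)
    wins, gpos, rows, codes, bits, bbin = [], [], [], [], [], []

    def track_add(diff, a, b):
        a, b = max(a, lo), min(b, hi)
        if a < b:
            diff[a - lo] += 1
            diff[b - lo] -= 1

    for r in sorted(reads, key=lambda r: (r.start, r.name, r.is_supplementary)):
        if r.chrom != chrom or r.is_secondary or r.is_duplicate:
            continue
        discordant = bool(r.is_paired and abs(abs(r.tlen) - stats.mean) >= cutoff)
        split = is_split_read(r, min_clip=min_clip)
        bits_total = (int(r.is_paired) + int(discordant)
                      + int(r.mapq > MAPQ_THRESHOLD) + int(split))
        bits_binary = (int(r.is_paired) << 3 | int(discordant) << 2
                       | int(r.mapq > MAPQ_THRESHOLD) << 1 | int(split))
        if split:
            track_add(d_split, r.start, r.reference_end)
        if discordant and r.is_primary and r.tlen > 0:
            track_add(d_disc, r.start, r.start + r.tlen)
        qoff, ref = 0, r.start
        for op, nlen in r.cigar:
            if op in "M=X":
                b0, b1 = ref, ref + nlen
                w0 = int(np.searchsorted(starts, b0 - WINDOW_BP + 1, side="left"))
                w1 = int(np.searchsorted(starts, b1, side="left"))
                for w in range(w0, w1):
                    ws = int(starts[w])
                    p0, p1 = max(b0, ws), min(b1, ws + WINDOW_BP)
                    if p0 >= p1:
                        continue
                    cols = np.arange(p0 - ws, p1 - ws)
                    rows.append(rank[w, cols].copy())
                    rank[w, cols] += 1
                    wins.append(np.full(cols.size, w, dtype=np.int32))
                    gpos.append(np.arange(p0, p1, dtype=np.int64))
                    codes.append(_BASE_CODE[np.frombuffer(
                        r.seq[qoff + p0 - ref: qoff + p1 - ref].encode("ascii"),
                        dtype=np.uint8)])
                    bits.append(np.full(cols.size, bits_total, dtype=np.int32))
                    bbin.append(np.full(cols.size, bits_binary, dtype=np.int32))
                ref += nlen
                qoff += nlen
            elif op in "DN":
                ref += nlen
            elif op in "SI":
                qoff += nlen

    if not wins:
        return canvas
    wins = np.concatenate(wins)
    gpos = np.concatenate(gpos)
    rows = np.concatenate(rows)
    codes = np.concatenate(codes)
    bits = np.concatenate(bits)
    bbin = np.concatenate(bbin)
    keep = rows < depth_scale
    wins, gpos, rows, codes, bits, bbin = (
        a[keep] for a in (wins, gpos, rows, codes, bits, bbin))

    n_disc = np.cumsum(d_disc[:-1])[gpos - lo]
    n_split = np.cumsum(d_split[:-1])[gpos - lo]
    col_aux = np.clip(n_disc + n_split, 0, AUX_MAX)
    colors = _pixel_colors(codes, col_aux, n_disc, bits, bbin)
    wstart = starts[wins]
    y = IMAGE_SIZE - 1 - rows
    x = MARGIN + (gpos - wstart).astype(np.int64) * COLUMN_WIDTH
    canvas[wins[:, None], y[:, None], x[:, None] + np.arange(COLUMN_WIDTH)] = \
        colors[:, None, :]
    return canvas


def label_window(start: int, end: int, truth: Sequence[tuple[int, int]],
                 overlap_threshold: float = 0.5) -> int:
    """1 iff at least ``overlap_threshold`` of the window lies inside a deletion."""
    width = end - start
    covered = 0
    for t0, t1 in truth:
        covered += max(0, min(end, t1) - max(start, t0))
    return int(covered >= overlap_threshold * width)
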