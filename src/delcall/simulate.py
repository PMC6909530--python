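"""Paired-end read simulator with exact deletion signatures.

Generates a random reference, applies homozygous/heterozygous deletions to a
diploid donor, and draws paired-end fragments whose reads are mapped back to
the reference *analytically* through the donor->reference coordinate map.  A
read whose donor span crosses a deletion junction becomes a split record
(soft-clipped primary plus a supplementary record for the clipped part), and a
pair whose fragment brackets a deletion acquires an observed insert inflated by
exactly the deletion length — the split-read and discordant-pair signatures of
real aligners, without running one.

The library defaults emulate a typical high-throughput paired-end run:
100 bp reads, insert mean 456 bp with standard deviation ~60 bp, and mean
depth configurable in the 10-60x range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import AlignedRead

MIN_DELETION_LENGTH = 50   # deletions shorter than this are not "long"
MIN_SUPPLEMENTARY_SEGMENT = 15


@dataclass(frozen=True)
class DeletionSpec:
    """A deletion on the reference, 0-based half-open."""

    chrom: str
    start: int
    end: int
    zygosity: str = "homozygous"  # or "heterozygous"

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("deletion start must be >= 0")
        if self.end - self.start < MIN_DELETION_LENGTH:
            raise ValueError(
                f"deletion [{self.start}, {self.end}) shorter than "
                f"{MIN_DELETION_LENGTH} bp")
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LibraryModel:
    """Sequencing-library parameters (all lengths in bases)."""

    read_length: int = 100
    insert_mean: float = 456.0
    insert_sd: float = 60.0
    coverage: float = 30.0

    def __post_init__(self):
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed 2 * read_length")
        if self.insert_sd <= 0 or self.coverage <= 0:
            raise ValueError("insert_sd and coverage must be positive")


def simulate_reference(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """Draw an i.i.d. reference sequence with the given GC fraction."""
    if length <= 0:
        raise ValueError("reference length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be a fraction in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return bases.tobytes().decode("ascii")


class HaplotypeMap:
    """Donor->reference coordinate map for one haplotype.

    The haplotype is the concatenation of the reference intervals that survive
    the haplotype's deletions; mapping is exact and invertible on kept bases.
    """

    def __init__(self, kept: list[tuple[int, int]]):
        self.kept = kept
        lengths = np.array([e - s for s, e in kept], dtype=np.int64)
        self.donor_starts = np.concatenate([[0], np.cumsum(lengths)])[:-1]
        self.ref_starts = np.array([s for s, _ in kept], dtype=np.int64)
        self.lengths = lengths
        self.donor_length = int(lengths.sum())

    def to_reference(self, donor_pos: int) -> int:
        i = int(np.searchsorted(self.donor_starts, donor_pos, side="right")) - 1
        off = donor_pos - self.donor_starts[i]
        if off >= self.lengths[i]:
            raise IndexError("donor position out of range")
        return int(self.ref_starts[i] + off)

    def to_donor(self, ref_pos: int) -> int:
        """Inverse map; raises KeyError for deleted reference positions."""
        i = int(np.searchsorted(self.ref_starts, ref_pos, side="right")) - 1
        if i < 0 or ref_pos >= self.ref_starts[i] + self.lengths[i]:
            raise KeyError(f"reference position {ref_pos} is deleted on this haplotype")
        return int(self.donor_starts[i] + (ref_pos - self.ref_starts[i]))

    def map_interval(self, d0: int, d1: int) -> list[tuple[int, int]]:
        """Map donor interval [d0, d1) to maximal contiguous reference pieces."""
        pieces = []
        i = int(np.searchsorted(self.donor_starts, d0, side="right")) - 1
        while d0 < d1:
            seg_end = self.donor_starts[i] + self.lengths[i]
            take = int(min(d1, seg_end) - d0)
            rs = int(self.ref_starts[i] + (d0 - self.donor_starts[i]))
            pieces.append((rs, rs + take))
            d0 += take
            i += 1
        return pieces


def apply_deletions(reference: str, specs: list[DeletionSpec]
                    ) -> tuple[list[str], list[HaplotypeMap]]:
    """Build the two donor haplotypes and their coordinate maps.

    Homozygous deletions are removed from both haplotypes; heterozygous
    deletions are assigned to alternating haplotypes in genomic order.
    """
    ordered = sorted(specs, key=lambda d: d.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping deletions at {a.start}-{a.end} / {b.start}-{b.end}")
    if ordered and ordered[-1].end > len(reference):
        raise ValueError("deletion extends past the end of the reference")

    het_toggle = 0
    per_hap: list[list[DeletionSpec]] = [[], []]
    for d in ordered:
        if d.zygosity == "homozygous":
            per_hap[0].append(d)
            per_hap[1].append(d)
        else:
            per_hap[het_toggle].append(d)
            het_toggle ^= 1

    haplotypes, maps = [], []
    for dels in per_hap:
        kept, pos = [], 0
        for d in dels:
            if d.start > pos:
                kept.append((pos, d.start))
            pos = d.end
        if pos < len(reference):
            kept.append((pos, len(reference)))
        hmap = HaplotypeMap(kept)
        haplotypes.append("".join(reference[s:e] for s, e in kept))
        maps.append(hmap)
    return haplotypes, maps


def _reads_for_interval(name: str, chrom: str, hap: str, hmap: HaplotypeMap,
                        d0: int, d1: int, is_read2: bool, is_reverse: bool,
                        ) -> list[AlignedRead]:
    """Map one read's donor interval; emit primary (+ supplementary) records."""
    pieces = hmap.map_interval(d0, d1)
    seq = hap[d0:d1]
    if len(pieces) == 1:
        rs, re_ = pieces[0]
        return [AlignedRead(name=name, chrom=chrom, start=rs, mapq=60,
                            cigar=[("M", re_ - rs)], seq=seq,
                            is_read2=is_read2, is_reverse=is_reverse)]
    # split read: primary = longest piece, soft clips for the rest
    sizes = [e - s for s, e in pieces]
    primary_i = int(np.argmax(sizes))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    out = []
    order = [primary_i] + [i for i in range(len(pieces)) if i != primary_i]
    for rank, i in enumerate(order):
        if rank > 0 and sizes[i] < MIN_SUPPLEMENTARY_SEGMENT:
            continue
        pre, post = int(offsets[i]), int(offsets[-1] - offsets[i + 1])
        cigar = []
        if pre:
            cigar.append(("S", pre))
        cigar.append(("M", sizes[i]))
        if post:
            cigar.append(("S", post))
        out.append(AlignedRead(name=name, chrom=chrom, start=pieces[i][0],
                               mapq=60, cigar=cigar, seq=seq,
                               is_read2=is_read2, is_reverse=is_reverse,
                               is_supplementary=rank > 0))
    return out


def simulate_alignments(haplotypes: list[str], maps: list[HaplotypeMap],
                        lib: LibraryModel, seed: int = 0, chrom: str = "chr1",
                        error_rate: float = 0.0) -> list[AlignedRead]:
    """Draw paired-end fragments and map their reads back to the reference.

    Fragment inserts are Normal(insert_mean, insert_sd) truncated below at
    2*read_length.  Each haplotype receives half of the target coverage.
    Records come back coordinate-sorted.
    """
    rng = np.random.default_rng(seed)
    rl = lib.read_length
    reads: list[AlignedRead] = []
    for hap_i, (hap, hmap) in enumerate(zip(haplotypes, maps)):
        hlen = len(hap)
        if hlen < 2 * rl:
            raise ValueError("haplotype shorter than one fragment; deletions too large?")
        n_frags = int(round(lib.coverage / 2 * hlen / (2 * rl)))
        inserts = rng.normal(lib.insert_mean, lib.insert_sd, size=n_frags)
        inserts = np.maximum(np.rint(inserts).astype(np.int64), 2 * rl)
        inserts = np.minimum(inserts, hlen)
        starts = np.floor(rng.random(n_frags) * (hlen - inserts + 1)).astype(np.int64)
        for k in range(n_frags):
            s, ins = int(starts[k]), int(inserts[k])
            name = f"frag_h{hap_i}_{k}"
            recs = _reads_for_interval(name, chrom, hap, hmap, s, s + rl,
                                       is_read2=False, is_reverse=False)
            recs += _reads_for_interval(name, chrom, hap, hmap,
                                        s + ins - rl, s + ins,
                                        is_read2=True, is_reverse=True)
            prim1 = next(r for r in recs if not r.is_supplementary and not r.is_read2)
            prim2 = next(r for r in recs if not r.is_supplementary and r.is_read2)
            tlen = (max(prim1.reference_end, prim2.reference_end)
                    - min(prim1.start, prim2.start))
            left_is_read2 = prim2.start < prim1.start
            for r in recs:
                r.mate_start = (prim1 if r.is_read2 else prim2).start
                r.tlen = tlen if r.is_read2 == left_is_read2 else -tlen
            reads.extend(recs)
    if error_rate > 0:
        _inject_errors(reads, error_rate, rng)
    reads.sort(key=lambda r: (r.chrom, r.start, r.name, r.is_supplementary, r.is_read2))
    return reads


def _inject_errors(reads: list[AlignedRead], rate: float, rng: np.random.Generator):
    alphabet = "ACGT"
    for r in reads:
        n_err = rng.binomial(len(r.seq), rate)
        if n_err == 0:
            continue
        seq = list(r.seq)
        for pos in rng.integers(0, len(seq), size=n_err):
            seq[pos] = alphabet[(alphabet.index(seq[pos]) + int(rng.integers(1, 4))) % 4]
        r.seq = "".join(seq)


@dataclass
class Scene:
    """A simulated study scene: reference, truth deletions and mapped reads."""

    chrom: str
    reference: str
    deletions: list[DeletionSpec]
    lib: LibraryModel
    reads: list[AlignedRead] = field(repr=False, default_factory=list)

    @property
    def length(self) -> int:
        return len(self.reference)


def simulate_scene(length: int, deletions: list[DeletionSpec] | None = None,
                   lib: LibraryModel | None = None, seed: int = 0,
                   chrom: str = "chr1", gc: float = 0.41,
                   error_rate: float = 0.0) -> Scene:
    """End-to-end convenience: reference + donor + alignments in one call."""
    lib = lib or LibraryModel()
    deletions = deletions or []
    reference = simulate_reference(length, gc=gc, seed=seed)
    haps, maps = apply_deletions(reference, deletions)
    reads = simulate_alignments(haps, maps, lib, seed=seed + 1, chrom=chrom,
                                error_rate=error_rate)
    return Scene(chrom=chrom, reference=reference, deletions=sorted(
        deletions, key=lambda d: d.start), lib=lib, reads=reads)


def random_deletions(n: int, genome_length: int, size_range: tuple[int, int],
                     seed: int = 0, chrom: str = "chr1",
                     zygosity: str = "mixed", margin: int = 2000,
                     spacing: int = 2000) -> list[DeletionSpec]:
    """Place n non-overlapping deletions uniformly, keeping them apart.

    ``zygosity``: "homozygous", "heterozygous" or "mixed" (alternating).
    """
    rng = np.random.default_rng(seed)
    specs: list[DeletionSpec] = []
    taken: list[tuple[int, int]] = []
    tries = 0
    while len(specs) < n:
        tries += 1
        if tries > 200 * n:
            raise ValueError("could not place deletions; genome too small")
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        start = int(rng.integers(margin, genome_length - margin - size))
        if any(start - spacing < e and s < start + size + spacing for s, e in taken):
            continue
        zyg = (zygosity if zygosity != "mixed"
               else ("homozygous" if len(specs) % 2 == 0 else "heterozygous"))
        specs.append(DeletionSpec(chrom, start, start + size, zyg))
        taken.append((start, start + size))
    return sorted(specs, key=lambda d: d.start)
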