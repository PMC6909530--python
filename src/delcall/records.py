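"""Alignment record container and standard-format IO (SAM via pysam, FASTA, VCF).

The in-memory representation is a lightweight :class:`AlignedRead` rather than a
:class:`pysam.AlignedSegment`, so that the simulator can build records without a
round trip through a file and the feature extractor can iterate millions of
records cheaply.  Conversion to and from SAM preserves flags, CIGAR, mapping
quality and the observed template length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

CIGAR_OPS = "MIDNSHP=X"
_CONSUMES_REF = set("MDN=X")
_CONSUMES_QUERY = set("MIS=X")


@dataclass(slots=True)
class AlignedRead:
    """A single mapped read segment (primary or supplementary)."""

    name: str
    chrom: str
    start: int                      # 0-based leftmost reference position
    mapq: int
    cigar: list[tuple[str, int]]    # [(op, length), ...]
    seq: str
    is_paired: bool = True
    is_reverse: bool = False
    is_read2: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    mate_start: int = -1
    tlen: int = 0                   # signed observed template length (outer span)

    @property
    def reference_end(self) -> int:
        """One past the last reference position consumed by this alignment."""
        return self.start + sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _CONSUMES_QUERY)

    @property
    def clip_lengths(self) -> tuple[int, int]:
        """(leading, trailing) soft/hard clip lengths."""
        lead = self.cigar[0][1] if self.cigar and self.cigar[0][0] in "SH" else 0
        trail = self.cigar[-1][1] if len(self.cigar) > 1 and self.cigar[-1][0] in "SH" else 0
        return lead, trail

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals consumed by M/=/X operations."""
        blocks = []
        pos = self.start
        for op, n in self.cigar:
            if op in "M=X":
                blocks.append((pos, pos + n))
                pos += n
            elif op in "DN":
                pos += n
        return blocks

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def parse_cigar(cigarstring: str) -> list[tuple[str, int]]:
    if not cigarstring or cigarstring == "*":
        raise ValueError(f"unparseable CIGAR: {cigarstring!r}")
    out: list[tuple[str, int]] = []
    num = ""
    for ch in cigarstring:
        if ch.isdigit():
            num += ch
        elif ch in CIGAR_OPS:
            if not num:
                raise ValueError(f"unparseable CIGAR: {cigarstring!r}")
            out.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"unparseable CIGAR: {cigarstring!r}")
    if num:
        raise ValueError(f"unparseable CIGAR: {cigarstring!r}")
    return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(path: str, reads: Sequence[AlignedRead],
              references: dict[str, int]) -> None:
    """Write coordinate-sorted reads to a SAM (or BAM, by extension) file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    mode = "wb" if str(path).endswith(".bam") else "w"
    tid = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar_string()
            a.query_sequence = r.seq or None
            flag = 0
            if r.is_paired:
                flag |= 0x1 | 0x2  # paired; pair flagged proper by the simulator
                flag |= 0x80 if r.is_read2 else 0x40
                if not r.is_reverse:
                    flag |= 0x20  # FR library: mate on the opposite strand
            if r.is_reverse:
                flag |= 0x10
            if r.is_secondary:
                flag |= 0x100
            if r.is_duplicate:
                flag |= 0x400
            if r.is_supplementary:
                flag |= 0x800
            a.flag = flag
            if r.is_paired:
                a.next_reference_id = tid[r.chrom]
                a.next_reference_start = r.mate_start
                a.template_length = r.tlen
            out.write(a)


def read_sam(path: str) -> list[AlignedRead]:
    """Load SAM/BAM records into :class:`AlignedRead` objects (unmapped skipped)."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.cigarstring is None:
                continue
            reads.append(AlignedRead(
                name=a.query_name,
                chrom=a.reference_name,
                start=a.reference_start,
                mapq=a.mapping_quality,
                cigar=[(CIGAR_OPS[op], n) for op, n in a.cigartuples],
                seq=a.query_sequence or "",
                is_paired=a.is_paired,
                is_reverse=a.is_reverse,
                is_read2=a.is_read2,
                is_secondary=a.is_secondary,
                is_supplementary=a.is_supplementary,
                is_duplicate=a.is_duplicate,
                mate_start=a.next_reference_start if a.is_paired else -1,
                tlen=a.template_length,
            ))
    return reads


# ---------------------------------------------------------------------------
# FASTA / VCF
# ---------------------------------------------------------------------------

def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=CONTIGS>
##ALT=<ID=DEL,Description="Deletion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise structural variation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
"""


def write_deletions_vcf(path: str, deletions: Iterable, sample: str = "sim") -> None:
    """Write deletion intervals as VCF 4.2 DEL records.

    ``deletions`` yields objects with 0-based half-open ``start``/``end``,
    ``chrom`` and optionally ``zygosity`` / ``imprecise`` attributes.  The
    standard SV convention is used: POS is the base before the deletion,
    END the last deleted base (both 1-based); SVLEN is negative.
    """
    deletions = list(deletions)
    contigs = sorted({d.chrom for d in deletions}) or ["chr1"]
    header = VCF_HEADER.replace("SAMPLE", sample)
    header = header.replace(
        "##contig=<ID=CONTIGS>\n",
        "".join(f"##contig=<ID={c}>\n" for c in contigs))
    with open(path, "w") as fh:
        fh.write(header)
        for d in deletions:
            gt = "1/1" if getattr(d, "zygosity", "homozygous") == "homozygous" else "0/1"
            info = f"SVTYPE=DEL;END={d.end};SVLEN={-(d.end - d.start)}"
            if getattr(d, "imprecise", False):
                info += ";IMPRECISE"
            fh.write(f"{d.chrom}\t{d.start}\t.\tN\t<DEL>\t.\tPASS\t{info}\tGT\t{gt}\n")


def read_deletions_vcf(path: str) -> list[tuple[str, int, int, str]]:
    """Parse DEL records back to (chrom, start0, end0, zygosity) tuples."""
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.info.get("SVTYPE") != "DEL":
                continue
            end = rec.stop   # END (or POS + |SVLEN|): 1-based last deleted base
            gt = "heterozygous"
            for s in rec.samples.values():
                if s.get("GT") in ((1, 1),):
                    gt = "homozygous"
            out.append((rec.chrom, rec.pos, int(end), gt))
    return out
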