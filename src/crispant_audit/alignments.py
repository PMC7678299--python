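"""Minimal aligned-read representation and SAM I/O (via pysam)."""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

CIGAR_OPS = "MIDNSHP=X"
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")
ALIGN_OPS = frozenset("M=X")  # ops aligning query bases to reference bases

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar))
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR string {cigar!r}")
    return ops


def cigar_to_str(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read; ``pos`` is the 0-based leftmost reference offset."""

    read_id: str
    chrom: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    mapq: int = 60
    seq: str = ""
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        for op, n in self.cigar:
            if op not in CIGAR_OPS or n < 1:
                raise ValueError(f"malformed CIGAR op ({op}, {n})")
        if self.seq:
            qlen = sum(n for op, n in self.cigar if op in QUERY_CONSUMING)
            if qlen != len(self.seq):
                raise ValueError(
                    f"CIGAR query length {qlen} != sequence length {len(self.seq)}"
                )

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in REF_CONSUMING)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference spans of M/=/X segments, merging blocks split by I only."""
        blocks: list[tuple[int, int]] = []
        ref = self.pos
        for op, n in self.cigar:
            if op in ALIGN_OPS:
                if blocks and blocks[-1][1] == ref:
                    blocks[-1] = (blocks[-1][0], ref + n)
                else:
                    blocks.append((ref, ref + n))
                ref += n
            elif op in ("D", "N"):
                ref += n
        return blocks

    def n_gaps(self) -> list[tuple[int, int]]:
        """Reference spans of N (spliced) gaps."""
        gaps: list[tuple[int, int]] = []
        ref = self.pos
        for op, n in self.cigar:
            if op == "N":
                gaps.append((ref, ref + n))
            if op in REF_CONSUMING:
                ref += n
        return gaps


def from_pysam(seg: pysam.AlignedSegment) -> AlignedRead:
    cigar = tuple(
        ("MIDNSHP=XB"[op], n) for op, n in (seg.cigartuples or ())
    )
    return AlignedRead(
        read_id=seg.query_name or "",
        chrom=seg.reference_name or "",
        pos=seg.reference_start,
        cigar=cigar,
        mapq=seg.mapping_quality,
        seq=seg.query_sequence or "",
        is_secondary=seg.is_secondary or seg.is_supplementary,
    )


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read all mapped records from a SAM/BAM file."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            reads.append(from_pysam(seg))
    return reads


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    sequence_lengths: dict[str, int],
) -> None:
    """Write reads to a (text) SAM file with a proper @SQ header."""
    names = list(sequence_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": n, "LN": sequence_lengths[n]} for n in names],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.reference_id = names.index(r.chrom)
            seg.reference_start = r.pos
            seg.mapping_quality = r.mapq
            seg.cigarstring = cigar_to_str(r.cigar)
            seg.query_sequence = r.seq or None
            seg.flag = 256 if r.is_secondary else 0
            out.write(seg)
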