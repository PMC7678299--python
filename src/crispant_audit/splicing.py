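"""Percentage of exon retention (PER) from spliced alignments.

PER for one exonic part in one sample is 100 * I / (I + E), where I counts
reads supporting inclusion of the part (enough aligned bases inside it) and
E counts reads supporting its exclusion (a spliced N-gap bridging the part
with well-anchored flanks). Reads whose gap only partially overlaps the part
are ambiguous and counted in neither.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .alignments import AlignedRead
from .genome import ExonicPart, GenomicInterval, TranscriptModel, translate


class InclusionExclusion(NamedTuple):
    inclusion: int
    exclusion: int
    ambiguous: int


@dataclass(frozen=True)
class PERResult:
    gene_id: str
    part_index: int
    sample_id: str
    inclusion_count: int
    exclusion_count: int
    ambiguous_count: int
    per: float | None  # percentage in [0, 100]; None when no informative reads


@dataclass(frozen=True)
class SkipConsequence:
    transcript_id: str
    part_index: int
    in_frame: bool
    aa_removed: int  # meaningful when in_frame
    frameshift: bool


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def count_inclusion_exclusion(
    reads: Sequence[AlignedRead],
    part: ExonicPart,
    gene: Sequence[TranscriptModel],
    min_anchor: int = 6,
) -> InclusionExclusion:
    """Count reads supporting inclusion vs exclusion of an exonic part.

    Inclusion: >= ``min_anchor`` aligned (M/=/X) bases inside the part.
    Exclusion: an N-gap fully covering the part whose flanking aligned
    blocks each overlap the gene's exonic sequence by >= ``min_anchor``.
    Multi-mapped (secondary) reads are skipped. A read can satisfy at most
    one of the two (a gap covering the part leaves no aligned bases in it).
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if not any(part.gene_id == t.gene_id for t in gene):
        raise ValueError(f"part belongs to gene {part.gene_id}, not this gene")
    exonic = [(e.start, e.end) for t in gene for e in t.exons]
    p = (part.interval.start, part.interval.end)
    chrom = part.interval.chrom

    inclusion = exclusion = ambiguous = 0
    for read in reads:
        if read.chrom != chrom or read.is_secondary:
            continue
        blocks = read.aligned_blocks()
        inside = sum(_overlap(b, p) for b in blocks)
        is_inclusion = inside >= min_anchor

        is_exclusion = False
        is_ambiguous = False
        for gap in read.n_gaps():
            if gap[0] <= p[0] and gap[1] >= p[1]:
                left = sum(_overlap(b, e) for b in blocks if b[1] <= gap[0] for e in exonic)
                right = sum(_overlap(b, e) for b in blocks if b[0] >= gap[1] for e in exonic)
                if left >= min_anchor and right >= min_anchor:
                    is_exclusion = True
            elif _overlap(gap, p) > 0:
                is_ambiguous = True

        if is_inclusion and is_exclusion:  # impossible by construction
            raise AssertionError("read supports both inclusion and exclusion")
        if is_inclusion:
            inclusion += 1
        elif is_exclusion:
            exclusion += 1
        elif is_ambiguous:
            ambiguous += 1
    return InclusionExclusion(inclusion, exclusion, ambiguous)


def per(inclusion_count: int, exclusion_count: int) -> float | None:
    """Percentage of exon retention; None when there are no informative reads."""
    if inclusion_count < 0 or exclusion_count < 0:
        raise ValueError("counts must be non-negative")
    total = inclusion_count + exclusion_count
    if total == 0:
        return None
    return 100.0 * inclusion_count / total


def per_result(
    reads: Sequence[AlignedRead],
    part: ExonicPart,
    gene: Sequence[TranscriptModel],
    sample_id: str = "",
    min_anchor: int = 6,
) -> PERResult:
    counts = count_inclusion_exclusion(reads, part, gene, min_anchor=min_anchor)
    return PERResult(
        part.gene_id,
        part.part_index,
        sample_id,
        counts.inclusion,
        counts.exclusion,
        counts.ambiguous,
        per(counts.inclusion, counts.exclusion),
    )


def skip_consequence(
    transcript: TranscriptModel,
    part: ExonicPart,
    reference: dict[str, str] | None = None,
) -> SkipConsequence:
    """Predict the protein consequence of skipping one exonic part.

    The removed CDS length is the part's overlap with the transcript's CDS.
    Skipping is in frame iff that length is divisible by 3 and (when a
    reference sequence is supplied) the fused junction introduces no stop
    codon; in-frame skipping removes length/3 amino acids.
    """
    if not any(e.overlaps(part.interval) for e in transcript.exons):
        raise ValueError(
            f"part {part.part_index} lies outside the exons of {transcript.transcript_id}"
        )
    if not transcript.cds:
        raise ValueError(f"transcript {transcript.transcript_id} is non-coding")

    removed = sum(c.overlap_length(part.interval) for c in transcript.cds)
    frameshift = removed % 3 != 0
    in_frame = not frameshift
    if in_frame and removed > 0 and reference is not None:
        seq = str(reference[transcript.chrom])
        pieces = []
        for c in transcript.cds:
            lo, hi = c.start, c.end
            if c.overlaps(part.interval):
                if part.interval.start > lo:
                    pieces.append(seq[lo : min(hi, part.interval.start)])
                if part.interval.end < hi:
                    pieces.append(seq[max(lo, part.interval.end) : hi])
            else:
                pieces.append(seq[lo:hi])
        cds_seq = "".join(pieces)
        if transcript.strand == "-":
            from .genome import reverse_complement

            cds_seq = reverse_complement(cds_seq)
        protein = translate(cds_seq[: len(cds_seq) - len(cds_seq) % 3])
        if "*" in protein[:-1]:
            in_frame = False
    return SkipConsequence(
        transcript.transcript_id,
        part.part_index,
        in_frame,
        removed // 3 if in_frame else 0,
        frameshift,
    )
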