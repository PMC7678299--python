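"""Indel quantification and mosaicism profiling at gRNA target sites.

The central statistic is the per-base proportion of indel-bearing reads in a
25 bp window centred on the Cas9 cut position, and its maximum over the
window. Reads are additionally tallied into indel alleles whose predicted
impact on the main transcript is classified into four categories
(HIGH / MODERATE / LOW / WT).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import AlignedRead, REF_CONSUMING, ALIGN_OPS
from .genome import GenomicInterval, TargetSite, TranscriptModel, reverse_complement, translate

CATEGORIES = ("HIGH", "MODERATE", "LOW", "WT")


@dataclass(frozen=True, order=True)
class IndelEvent:
    """One insertion or deletion in reference coordinates.

    Deletions: ``ref_pos`` is the first deleted base. Insertions: ``ref_pos``
    is the reference base immediately 5' of the inserted sequence (forward
    strand); the insertion sits between ``ref_pos`` and ``ref_pos + 1``.
    """

    kind: str  # "insertion" | "deletion"
    ref_pos: int
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise ValueError("inserted_seq length must equal event length")
        if self.kind == "deletion" and self.inserted_seq:
            raise ValueError("deletions carry no inserted sequence")

    def footprint(self) -> tuple[int, int]:
        """Reference span touched by the event (insertions: the two flanking bases)."""
        if self.kind == "deletion":
            return (self.ref_pos, self.ref_pos + self.length)
        return (self.ref_pos, self.ref_pos + 2)


@dataclass
class IndelProfile:
    site: TargetSite
    window: GenomicInterval
    per_base_proportion: np.ndarray  # NaN where coverage below min_coverage
    per_base_coverage: np.ndarray
    max_proportion: float  # NaN when no base meets min_coverage

    def to_records(self) -> list[dict]:
        return [
            {
                "chrom": self.window.chrom,
                "pos": self.window.start + i,
                "coverage": int(self.per_base_coverage[i]),
                "indel_reads": int(round(self.per_base_proportion[i] * self.per_base_coverage[i]))
                if self.per_base_coverage[i] > 0 and not math.isnan(self.per_base_proportion[i])
                else 0,
                "proportion": float(self.per_base_proportion[i]),
            }
            for i in range(len(self.per_base_coverage))
        ]


@dataclass(frozen=True)
class AlleleCount:
    allele_signature: str  # canonical serialization; "WT" for no indel
    read_count: int
    events: tuple[IndelEvent, ...] = ()


@dataclass(frozen=True)
class ImpactCall:
    allele_signature: str
    category: str  # HIGH / MODERATE / LOW / WT
    reason: str  # frameshift / stop_gained / splice_site / inframe_indel / noncoding / no_indel


@dataclass(frozen=True)
class ImpactComposition:
    sample_id: str
    fractions: Mapping[str, float]


def extract_indel_events(read: AlignedRead) -> list[IndelEvent]:
    """Extract I/D events from a read by walking its CIGAR along the reference."""
    events: list[IndelEvent] = []
    ref = read.pos
    query = 0
    for op, n in read.cigar:
        if op == "I":
            seq = read.seq[query : query + n] if read.seq else "N" * n
            events.append(IndelEvent("insertion", ref - 1, n, seq))
            query += n
        elif op == "D":
            events.append(IndelEvent("deletion", ref, n))
            ref += n
        else:
            if op in REF_CONSUMING:
                ref += n
            if op in ("M", "=", "X", "S"):
                query += n
    return events


#: canonical event order: by reference position, then kind/length/sequence
_EVENT_KEY = lambda e: (e.ref_pos, e.kind, e.length, e.inserted_seq)  # noqa: E731


def signature_of(events: Iterable[IndelEvent]) -> str:
    """Canonical text key of an indel allele; the empty allele is 'WT'."""
    parts = []
    for e in sorted(events, key=_EVENT_KEY):
        if e.kind == "deletion":
            parts.append(f"del@{e.ref_pos}:{e.length}")
        else:
            parts.append(f"ins@{e.ref_pos}:{e.inserted_seq}")
    return ";".join(parts) if parts else "WT"


def _covered_mask(read: AlignedRead, window: GenomicInterval) -> np.ndarray:
    """Window bases covered by the alignment (M/=/X/D consume; N gaps do not)."""
    mask = np.zeros(len(window), dtype=bool)
    ref = read.pos
    for op, n in read.cigar:
        if op in ALIGN_OPS or op == "D":
            lo = max(ref, window.start)
            hi = min(ref + n, window.end)
            if lo < hi:
                mask[lo - window.start : hi - window.start] = True
        if op in REF_CONSUMING:
            ref += n
    return mask


def indel_profile(
    reads: Sequence[AlignedRead],
    site: TargetSite,
    window_size: int = 25,
    min_coverage: int = 50,
    min_mapq: int = 20,
) -> IndelProfile:
    """Per-base indel proportions in a window centred on the cut position.

    For each window base the proportion is (#reads with a deletion spanning
    the base or an insertion anchored at it) / (#reads whose alignment covers
    the base). Bases with coverage below ``min_coverage`` are reported as
    missing (NaN) and excluded from ``max_proportion``.
    """
    window = site.window(window_size)
    w = len(window)
    coverage = np.zeros(w, dtype=int)
    indel_reads = np.zeros(w, dtype=int)

    for read in reads:
        if read.chrom != site.chrom or read.mapq < min_mapq or read.is_secondary:
            continue
        covered = _covered_mask(read, window)
        if not covered.any():
            continue
        coverage += covered
        hit = np.zeros(w, dtype=bool)
        for e in extract_indel_events(read):
            if e.kind == "deletion":
                lo = max(e.ref_pos, window.start)
                hi = min(e.ref_pos + e.length, window.end)
                if lo < hi:
                    hit[lo - window.start : hi - window.start] = True
            else:  # insertion attributed to its 5' anchor base
                if window.contains_pos(e.ref_pos):
                    hit[e.ref_pos - window.start] = True
        indel_reads += hit & covered

    with np.errstate(divide="ignore", invalid="ignore"):
        proportion = np.where(coverage > 0, indel_reads / np.maximum(coverage, 1), np.nan)
    proportion = np.where(coverage >= min_coverage, proportion, np.nan)
    max_prop = float(np.nanmax(proportion)) if np.any(~np.isnan(proportion)) else float("nan")
    return IndelProfile(site, window, proportion, coverage, max_prop)


def tally_alleles(
    reads: Sequence[AlignedRead],
    window: GenomicInterval,
    min_mapq: int = 20,
) -> tuple[list[AlleleCount], int]:
    """Group reads fully spanning the window by their canonical indel allele.

    Returns the allele counts (sorted by decreasing count, then signature)
    and the number of reads excluded for not fully covering the window.
    Insertions anchored at the base just 5' of the window are treated as
    inside it.
    """
    counts: dict[str, int] = {}
    rep_events: dict[str, tuple[IndelEvent, ...]] = {}
    excluded = 0
    for read in reads:
        if read.chrom != window.chrom or read.mapq < min_mapq or read.is_secondary:
            continue
        covered = _covered_mask(read, window)
        if not covered.all():
            excluded += 1
            continue
        in_window = []
        for e in extract_indel_events(read):
            if e.kind == "deletion":
                if e.ref_pos < window.end and e.ref_pos + e.length > window.start:
                    in_window.append(e)
            else:
                if window.start - 1 <= e.ref_pos < window.end:
                    in_window.append(e)
        sig = signature_of(in_window)
        counts[sig] = counts.get(sig, 0) + 1
        rep_events.setdefault(sig, tuple(sorted(in_window, key=_EVENT_KEY)))
    alleles = [
        AlleleCount(sig, n, rep_events[sig])
        for sig, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return alleles, excluded


def main_transcript(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """The transcript with the longest CDS (ties: lexicographically smallest id)."""
    coding = [t for t in transcripts if t.cds]
    if not coding:
        raise ValueError("gene has no coding transcript")
    return min(coding, key=lambda t: (-t.cds_length, t.transcript_id))


def _internal_boundaries(transcript: TranscriptModel) -> list[int]:
    bounds: list[int] = []
    exons = transcript.exons
    for i, e in enumerate(exons):
        if i > 0:
            bounds.append(e.start)  # acceptor side
        if i < len(exons) - 1:
            bounds.append(e.end)  # donor side
    return bounds


def _apply_events_to_cds(
    transcript: TranscriptModel,
    events: Sequence[IndelEvent],
    reference: Mapping[str, str],
) -> str:
    """Reconstruct the (forward-strand) CDS sequence with the allele applied."""
    seq = str(reference[transcript.chrom])
    pieces: list[str] = []
    for c in transcript.cds:
        piece = list(seq[c.start : c.end])
        for e in sorted(events, key=lambda e: -e.ref_pos):
            if e.kind == "deletion":
                lo = max(e.ref_pos, c.start) - c.start
                hi = min(e.ref_pos + e.length, c.end) - c.start
                if lo < hi:
                    del piece[lo:hi]
            else:
                if c.start <= e.ref_pos < c.end - 1:
                    piece.insert(e.ref_pos - c.start + 1, e.inserted_seq)
        pieces.append("".join(piece))
    cds_seq = "".join(pieces)
    if transcript.strand == "-":
        cds_seq = reverse_complement(cds_seq)
    return cds_seq


def classify_impact(
    allele: Sequence[IndelEvent],
    transcript: TranscriptModel,
    reference: Mapping[str, str] | None = None,
) -> ImpactCall:
    """Classify an indel allele's predicted impact on one transcript.

    Rules, in priority order: no indel -> WT; any event within 2 nt of an
    internal exon-intron boundary -> HIGH/splice_site; net CDS length change
    not divisible by 3 -> HIGH/frameshift; a new in-frame stop in the
    reconstructed CDS -> HIGH/stop_gained (requires ``reference``); other
    CDS-overlapping alleles -> MODERATE/inframe_indel; everything else
    (UTR/intron) -> LOW/noncoding.
    """
    sig = signature_of(allele)
    if not allele:
        return ImpactCall(sig, "WT", "no_indel")
    if not transcript.cds:
        raise ValueError(
            f"impact undefined for non-coding transcript {transcript.transcript_id}"
        )

    for b in _internal_boundaries(transcript):
        for e in allele:
            lo, hi = e.footprint()
            if lo < b + 2 and hi > b - 2:
                return ImpactCall(sig, "HIGH", "splice_site")

    ins_cds = 0
    del_cds = 0
    for e in allele:
        for c in transcript.cds:
            if e.kind == "deletion":
                del_cds += max(0, min(e.ref_pos + e.length, c.end) - max(e.ref_pos, c.start))
            else:
                # insertion lands inside the CDS only between two CDS bases
                if c.start <= e.ref_pos < c.end - 1:
                    ins_cds += e.length
    net = ins_cds - del_cds
    cds_overlap = ins_cds > 0 or del_cds > 0

    if net % 3 != 0:
        return ImpactCall(sig, "HIGH", "frameshift")
    if not cds_overlap:
        return ImpactCall(sig, "LOW", "noncoding")
    if reference is not None:
        protein = translate(_apply_events_to_cds(transcript, allele, reference))
        if "*" in protein[:-1]:
            return ImpactCall(sig, "HIGH", "stop_gained")
    return ImpactCall(sig, "MODERATE", "inframe_indel")


def impact_composition(
    alleles: Sequence[AlleleCount],
    calls: Mapping[str, ImpactCall],
    sample_id: str = "",
) -> ImpactComposition:
    """Read-weighted fraction of each impact category in one sample."""
    total = sum(a.read_count for a in alleles)
    sums = {c: 0 for c in CATEGORIES}
    for a in alleles:
        if a.allele_signature not in calls:
            raise ValueError(f"no impact call for allele {a.allele_signature!r}")
        sums[calls[a.allele_signature].category] += a.read_count
    fractions = {c: (sums[c] / total if total else float("nan")) for c in CATEGORIES}
    return ImpactComposition(sample_id, fractions)
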