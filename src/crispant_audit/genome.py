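"""Gene models, genomic coordinates and gRNA target sites.

All internal coordinates are 0-based half-open on the forward strand of the
reference; conversion from the 1-based inclusive GFF/GTF convention happens
only inside :func:`read_gene_models` / :func:`write_gene_models`.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: feature types treated as transcripts when reading annotation files
TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "lnc_RNA", "ncRNA", "tRNA", "rRNA",
    "snRNA", "snoRNA", "V_gene_segment", "C_gene_segment",
}
#: feature types counted as top-level gene records
GENE_TYPES = ("gene", "pseudogene")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons and (possibly empty) CDS intervals."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(self.cds, key=lambda c: c.start)))
        if not exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        chroms = {e.chrom for e in exons} | {c.chrom for c in self.cds}
        if len(chroms) != 1:
            raise ValueError("all intervals of a transcript must share one chromosome")
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in exons):
                raise ValueError(
                    f"CDS interval {c} of {self.transcript_id} not contained in an exon"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def tss(self) -> int:
        """0-based offset of the transcription start site (5'-most exon base)."""
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    def exonic_span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)


@dataclass(frozen=True)
class ExonicPart:
    """Minimal exon fragment from flattening all transcripts of one gene."""

    gene_id: str
    part_index: int  # 1-based, genomic-start order
    interval: GenomicInterval
    transcripts_containing: frozenset[str]


@dataclass(frozen=True)
class TargetSite:
    """A gRNA protospacer+PAM located on the reference.

    ``cut_pos`` is the 0-based offset of the first base 3' of the blunt
    Cas9 cut on the protospacer strand (cut between protospacer positions
    17 and 18, i.e. 3 bp 5' of the PAM).
    """

    name: str
    protospacer: str
    pam: str
    chrom: str
    cut_pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pam and not (len(self.pam) == 3 and self.pam[1:].upper() == "GG"):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def window(self, size: int = 25) -> GenomicInterval:
        """Window of ``size`` bases centred on the cut position."""
        if size % 2 == 0:
            raise ValueError("window size must be odd")
        half = size // 2
        return GenomicInterval(self.chrom, self.cut_pos - half, self.cut_pos + half + 1)


@dataclass
class AnnotationSet:
    """All gene models of one annotation plus reference sequence lengths."""

    genes: dict[str, list[TranscriptModel]]
    sequence_lengths: dict[str, int] = field(default_factory=dict)
    n_gene_records: int | None = None  # gene + pseudogene records in the source file

    def __post_init__(self) -> None:
        if self.n_gene_records is None:
            self.n_gene_records = len(self.genes)
        for gid, transcripts in self.genes.items():
            for t in transcripts:
                L = self.sequence_lengths.get(t.chrom)
                if L is not None and t.exons[-1].end > L:
                    raise ValueError(
                        f"transcript {t.transcript_id} exceeds length of {t.chrom}"
                    )

    def transcripts(self) -> Iterable[TranscriptModel]:
        for ts in self.genes.values():
            yield from ts


def _is_gtf(path: Path) -> bool:
    return path.suffix.lower() in {".gtf", ".gff2"}


def read_gene_models(path: str | Path) -> AnnotationSet:
    """Read a GFF3 or GTF file into an :class:`AnnotationSet`.

    1-based inclusive file coordinates become 0-based half-open. Transcripts
    are grouped under their genes; the count of top-level gene/pseudogene
    records is stored on the result and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gtf = _is_gtf(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=not gtf,
            disable_infer_transcripts=not gtf,
        )
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"cannot parse {path}: {exc}") from exc

    # orphan exons are a structural error, not something to silently drop
    for ex in db.features_of_type("exon"):
        if not list(db.parents(ex, level=1)):
            raise ValueError(f"exon without parent transcript at {ex.seqid}:{ex.start}")

    def _iv(f: gffutils.Feature) -> GenomicInterval:
        if f.strand not in STRANDS:
            raise ValueError(
                f"unknown strand symbol {f.strand!r} at {f.seqid}:{f.start}"
            )
        return GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)

    genes: dict[str, list[TranscriptModel]] = {}
    n_gene_records = 0
    for gtype in GENE_TYPES:
        for g in db.features_of_type(gtype):
            n_gene_records += 1
            gid = g.attributes.get("gene_id", [g.id])[0] if gtf else g.id
            transcripts: list[TranscriptModel] = []
            for t in db.children(g, level=1):
                if t.featuretype not in TRANSCRIPT_TYPES:
                    continue
                exons = [_iv(e) for e in db.children(t, featuretype="exon")]
                cds = [_iv(c) for c in db.children(t, featuretype="CDS")]
                if not exons:
                    continue
                tid = t.attributes.get("transcript_id", [t.id])[0] if gtf else t.id
                transcripts.append(
                    TranscriptModel(tid, gid, tuple(exons), tuple(cds), t.strand)
                )
            if transcripts:
                genes[gid] = transcripts

    seq_lengths: dict[str, int] = {}
    for line in db.directives:
        fields = line.split()
        if fields and fields[0] == "sequence-region" and len(fields) >= 4:
            seq_lengths[fields[1]] = int(fields[3])
    if not seq_lengths:
        for f in db.all_features():
            seq_lengths[f.seqid] = max(seq_lengths.get(f.seqid, 0), f.end)

    logger.info("read %d gene records (%d with transcripts) from %s",
                n_gene_records, len(genes), path)
    return AnnotationSet(genes, seq_lengths, n_gene_records=n_gene_records)


def write_gene_models(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet back to GFF3 (inverse of :func:`read_gene_models`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(ann.sequence_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gid in ann.genes:
            ts = ann.genes[gid]
            g_start = min(t.exons[0].start for t in ts)
            g_end = max(t.exons[-1].end for t in ts)
            chrom, strand = ts[0].chrom, ts[0].strand
            fh.write(
                f"{chrom}\tcrispant_audit\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gid}\n"
            )
            for t in ts:
                fh.write(
                    f"{chrom}\tcrispant_audit\tmRNA\t{t.exons[0].start + 1}\t"
                    f"{t.exons[-1].end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gid}\n"
                )
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{e.chrom}\tcrispant_audit\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                for i, c in enumerate(t.cds, 1):
                    fh.write(
                        f"{c.chrom}\tcrispant_audit\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{t.strand}\t.\tID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n"
                    )


def flatten_exonic_parts(transcripts: Sequence[TranscriptModel]) -> list[ExonicPart]:
    """Partition the exon union of one gene at every transcript exon boundary.

    Parts are numbered 1..n in genomic-start order regardless of strand, so a
    part index refers to the same genomic fragment in every transcript.
    """
    if not transcripts:
        raise ValueError("flatten_exonic_parts requires at least one transcript")
    gene_ids = {t.gene_id for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    if len(gene_ids) != 1 or len(chroms) != 1 or len(strands) != 1:
        raise ValueError("all transcripts must share gene_id, chromosome and strand")
    gene_id, chrom, strand = gene_ids.pop(), chroms.pop(), strands.pop()

    bounds = sorted({b for t in transcripts for e in t.exons for b in (e.start, e.end)})
    parts: list[ExonicPart] = []
    index = 1
    for s, e in zip(bounds, bounds[1:]):
        containing = frozenset(
            t.transcript_id
            for t in transcripts
            if any(x.start <= s and e <= x.end for x in t.exons)
        )
        if containing:
            parts.append(
                ExonicPart(gene_id, index, GenomicInterval(chrom, s, e, strand), containing)
            )
            index += 1
    return parts


def part_exon_numbers(
    part: ExonicPart, transcripts: Sequence[TranscriptModel]
) -> dict[str, int]:
    """Map a part to the per-transcript exon ordinal (genomic order) containing it."""
    numbers: dict[str, int] = {}
    for t in transcripts:
        if t.transcript_id not in part.transcripts_containing:
            continue
        for i, e in enumerate(t.exons, 1):
            if e.start <= part.interval.start and part.interval.end <= e.end:
                numbers[t.transcript_id] = i
                break
    return numbers


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


#: offset of the blunt cut's first 3' base from a plus-strand 23-mer match start
_CUT_OFFSET_PLUS = 17
#: same for a minus-strand match (PAM reverse complement leads the match)
_CUT_OFFSET_MINUS = 5


def locate_target_site(
    protospacer_with_pam: str,
    reference: Mapping[str, str],
    name: str = "site",
) -> list[TargetSite]:
    """Locate every exact occurrence of a 23-nt protospacer+PAM query.

    Both strands are searched; each match yields a :class:`TargetSite` with
    the blunt-cut position 3 bp 5' of the PAM. A single gRNA may match
    several loci (multi-gene targeting), so all hits are returned.
    """
    q = protospacer_with_pam.upper()
    if len(q) != 23:
        raise ValueError("query must be a 23-nt protospacer + PAM")
    if q[21:23] != "GG":
        raise ValueError("query does not end in an NGG PAM")
    protospacer, pam = q[:20], q[20:]
    rc = reverse_complement(q)

    hits: list[TargetSite] = []
    for chrom in reference:
        seq = str(reference[chrom]).upper()
        for o in _find_all(seq, q):
            hits.append(TargetSite(name, protospacer, pam, chrom, o + _CUT_OFFSET_PLUS, "+"))
        for o in _find_all(seq, rc):
            hits.append(TargetSite(name, protospacer, pam, chrom, o + _CUT_OFFSET_MINUS, "-"))
    if not hits:
        warnings.warn(f"no match for target {name!r} in the reference", stacklevel=2)
    return hits


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a plain {name: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def translate(seq: str) -> str:
    return str(Seq(seq).translate())
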