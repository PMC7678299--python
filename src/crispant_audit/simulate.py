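"""Synthetic-data generators with ground-truth tables.

Three generators cover the analysis stages: mosaic amplicon reads drawn from
an indel-allele spectrum at a gRNA target site, spliced reads from a toy
gene with a controlled exon-inclusion level, and negative-binomial count
matrices for a two-strain x two-diet design with planted log2 fold changes
and an optional phenotype covariate. Every generator is a pure function of
its arguments, including the seed, and emits a truth table recording the
allele / isoform / effect of every simulated unit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignedRead
from .genome import ExonicPart, GenomicInterval, TargetSite, TranscriptModel
from .mosaicism import IndelEvent, signature_of
from .expression import CountsMatrix, SampleMeta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlleleSpectrum:
    """Mapping of indel alleles (tuples of events; empty = WT) to fractions."""

    entries: tuple[tuple[tuple[IndelEvent, ...], float], ...]

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.entries]
        if any(f <= 0 for f in fracs):
            raise ValueError("allele fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("allele fractions must sum to 1")

    @property
    def alleles(self) -> list[tuple[IndelEvent, ...]]:
        return [a for a, _ in self.entries]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.entries])

    @property
    def signatures(self) -> list[str]:
        return [signature_of(a) for a in self.alleles]


@dataclass
class SimTruth:
    """Ground truth for one simulated scenario."""

    scenario: str
    params: dict
    table: pd.DataFrame


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# mosaic amplicon reads


def _build_read_seq(
    reference: str, pos: int, events: Sequence[IndelEvent], read_len: int
) -> tuple[str, tuple[tuple[str, int], ...]]:
    """Apply an allele's indels to the reference from ``pos``, emitting
    exactly ``read_len`` query bases and the matching CIGAR."""
    dels = {e.ref_pos: e for e in events if e.kind == "deletion"}
    ins = {e.ref_pos: e for e in events if e.kind == "insertion"}
    seq: list[str] = []
    cigar: list[list] = []  # [op, n]

    def push(op: str, n: int) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += n
        else:
            cigar.append([op, n])

    ref_i = pos
    remaining = read_len
    while remaining > 0 and ref_i < len(reference):
        d = dels.get(ref_i)
        if d is not None:
            if cigar:  # a deletion before any aligned base shifts the start
                push("D", d.length)
            ref_i += d.length
            continue
        seq.append(reference[ref_i])
        push("M", 1)
        remaining -= 1
        e = ins.get(ref_i)
        if e is not None and remaining > 0:
            take = min(e.length, remaining)
            seq.append(e.inserted_seq[:take])
            push("I", take)
            remaining -= take
        ref_i += 1
    while cigar and cigar[-1][0] == "D":
        cigar.pop()
    return "".join(seq), tuple((op, n) for op, n in cigar)


def simulate_mosaic_amplicons(
    reference: str,
    site: TargetSite,
    spectrum: AlleleSpectrum,
    n_reads: int = 2000,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    window_size: int = 25,
) -> tuple[list[AlignedRead], SimTruth]:
    """Amplicon reads drawn multinomially from an indel-allele spectrum.

    Every read fully covers the target window. Substitution errors (at
    ``error_rate`` per base) never create or destroy indels, so the per-read
    allele truth is unambiguous.
    """
    rng = np.random.default_rng(seed)
    window = site.window(window_size)
    alleles = spectrum.alleles
    sigs = spectrum.signatures

    starts_lo: list[int] = []
    starts_hi: list[int] = []
    for allele in alleles:
        ins_total = sum(e.length for e in allele if e.kind == "insertion")
        del_total = sum(e.length for e in allele if e.kind == "deletion")
        lo = max(0, window.end - read_len + ins_total)
        hi = min(window.start, len(reference) - (read_len - ins_total + del_total))
        if hi < lo:
            raise ValueError(
                f"read length {read_len} cannot cover the {len(window)} bp window "
                f"for allele {signature_of(allele)!r}"
            )
        starts_lo.append(lo)
        starts_hi.append(hi)

    choice = rng.choice(len(alleles), size=n_reads, p=spectrum.fractions)
    reads: list[AlignedRead] = []
    truth_rows = []
    for i, a in enumerate(choice):
        pos = int(rng.integers(starts_lo[a], starts_hi[a] + 1))
        seq, cigar = _build_read_seq(reference, pos, alleles[a], read_len)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            # inserted bases are part of the allele definition: errors there
            # would silently change the allele signature, so exempt them
            eligible = np.zeros(len(arr), dtype=bool)
            q = 0
            for op, n in cigar:
                if op == "M":
                    eligible[q : q + n] = True
                if op in ("M", "I"):
                    q += n
            hit = np.flatnonzero((rng.random(len(arr)) < error_rate) & eligible)
            if hit.size:
                lut = np.zeros(256, dtype=np.int64)
                for j, b in enumerate(_BASES):
                    lut[b] = j
                shifts = rng.integers(1, 4, size=hit.size)
                arr[hit] = _BASES[(lut[arr[hit]] + shifts) % 4]
                seq = arr.tobytes().decode()
        read_id = f"amp{i:05d}"
        reads.append(AlignedRead(read_id, site.chrom, pos, cigar, mapq=60, seq=seq))
        truth_rows.append({"read_id": read_id, "allele_signature": sigs[a]})

    truth = SimTruth(
        scenario="mosaic_amplicons",
        params={
            "site": site.name,
            "spectrum": dict(zip(sigs, spectrum.fractions.tolist())),
            "n_reads": n_reads,
            "read_len": read_len,
            "error_rate": error_rate,
            "seed": seed,
        },
        table=pd.DataFrame(truth_rows),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# spliced reads with a controlled inclusion level


def make_skip_isoform(transcript: TranscriptModel, part: ExonicPart) -> TranscriptModel:
    """The transcript with one exonic part removed from its exons."""
    p = part.interval
    exons: list[GenomicInterval] = []
    for e in transcript.exons:
        if not e.overlaps(p):
            exons.append(e)
            continue
        if e.start < p.start:
            exons.append(GenomicInterval(e.chrom, e.start, p.start, e.strand))
        if p.end < e.end:
            exons.append(GenomicInterval(e.chrom, p.end, e.end, e.strand))
    if not exons:
        raise ValueError("removing the part leaves no exons")
    return TranscriptModel(
        transcript.transcript_id + "_skip",
        transcript.gene_id,
        tuple(exons),
        (),
        transcript.strand,
    )


def make_exon_skip_gene(
    chrom: str = "toy_chr",
    gene_id: str = "toy_gene",
    offset: int = 100,
    flank_len: int = 44,
    part_len: int = 66,
    intron_len: int = 80,
) -> tuple[TranscriptModel, TranscriptModel, ExonicPart]:
    """Three-exon toy gene whose middle exon is the skippable part.

    With the default geometry (44 nt flanking exons, 50 nt reads, anchor 6)
    every simulated fragment is informative for the retention statistic, so
    the expected PER equals 100 x the inclusion level.
    """
    e1 = GenomicInterval(chrom, offset, offset + flank_len)
    e2_start = e1.end + intron_len
    e2 = GenomicInterval(chrom, e2_start, e2_start + part_len)
    e3_start = e2.end + intron_len
    e3 = GenomicInterval(chrom, e3_start, e3_start + flank_len)
    inclusion = TranscriptModel(gene_id + "_t1", gene_id, (e1, e2, e3), (e1, e2, e3), "+")
    part = ExonicPart(gene_id, 2, e2, frozenset({inclusion.transcript_id}))
    return inclusion, make_skip_isoform(inclusion, part), part


def _project_to_genome(
    exons: Sequence[GenomicInterval], t_start: int, length: int
) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Map a transcript-coordinate fragment onto genomic blocks with N gaps."""
    cigar: list[list] = []
    pos = None
    remaining = length
    cursor = 0
    prev_end = None
    for e in exons:
        e_len = len(e)
        if cursor + e_len <= t_start:
            cursor += e_len
            continue
        within = max(0, t_start - cursor)
        take = min(e_len - within, remaining)
        g_start = e.start + within
        if pos is None:
            pos = g_start
        else:
            gap = g_start - prev_end
            if gap > 0:
                cigar.append(["N", gap])
        cigar.append(["M", take])
        prev_end = g_start + take
        remaining -= take
        cursor += e_len
        if remaining == 0:
            break
    if remaining > 0 or pos is None:
        raise ValueError("fragment extends beyond the isoform")
    return pos, tuple((op, n) for op, n in cigar)


def simulate_spliced_reads(
    inclusion_isoform: TranscriptModel,
    part: ExonicPart,
    inclusion_level: float,
    n_fragments: int = 5000,
    read_len: int = 50,
    seed: int = 0,
    skip_isoform: TranscriptModel | None = None,
    reference: Mapping[str, str] | None = None,
) -> tuple[list[AlignedRead], SimTruth]:
    """Single-end spliced reads at a controlled exon-inclusion level.

    Each fragment comes from the inclusion isoform with probability
    ``inclusion_level``, otherwise from the skip isoform (the inclusion
    isoform minus the part); fragment starts are uniform along the chosen
    isoform and reads are projected to genomic coordinates with N gaps at
    introns and at the skipped part.
    """
    if not 0.0 <= inclusion_level <= 1.0:
        raise ValueError("inclusion_level must lie in [0, 1]")
    if skip_isoform is None:
        skip_isoform = make_skip_isoform(inclusion_isoform, part)
    isoforms = (inclusion_isoform, skip_isoform)
    iso_lens = [sum(len(e) for e in iso.exons) for iso in isoforms]
    for iso, L in zip(isoforms, iso_lens):
        if read_len > L:
            raise ValueError(f"read length {read_len} exceeds isoform {iso.transcript_id} ({L} nt)")

    rng = np.random.default_rng(seed)
    chrom = inclusion_isoform.chrom
    ref_seq = str(reference[chrom]) if reference is not None else None
    use_incl = rng.random(n_fragments) < inclusion_level
    reads: list[AlignedRead] = []
    rows = []
    for i in range(n_fragments):
        iso_i = 0 if use_incl[i] else 1
        iso = isoforms[iso_i]
        t_start = int(rng.integers(0, iso_lens[iso_i] - read_len + 1))
        pos, cigar = _project_to_genome(iso.exons, t_start, read_len)
        if ref_seq is not None:
            pieces, r = [], pos
            for op, n in cigar:
                if op == "M":
                    pieces.append(ref_seq[r : r + n])
                if op in ("M", "N"):
                    r += n
            seq = "".join(pieces)
        else:
            seq = ""
        read_id = f"frag{i:05d}"
        reads.append(AlignedRead(read_id, chrom, pos, cigar, mapq=60, seq=seq))
        rows.append(
            {"read_id": read_id, "isoform": "inclusion" if iso_i == 0 else "skip"}
        )

    truth = SimTruth(
        scenario="spliced_reads",
        params={
            "gene_id": part.gene_id,
            "part_index": part.part_index,
            "inclusion_level": inclusion_level,
            "n_fragments": n_fragments,
            "read_len": read_len,
            "seed": seed,
        },
        table=pd.DataFrame(rows),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# NB count matrices for the 2 x 2 design


@dataclass(frozen=True)
class PhenotypeModel:
    """Simple DHA-like covariate: group shifts plus Gaussian noise, with an
    optional set of genes whose expression tracks the phenotype."""

    base: float = 10.0
    strain_delta: float = -3.0  # added for mutant strains
    diet_delta: float = -4.0  # added for the plant-oil diet
    sd: float = 1.0
    n_correlated: int = 0
    slope: float = 0.0  # log2-expression change per phenotype SD


def default_design(n_per_group: int = 6, strains: Sequence[str] = ("WT", "d6abc5_mt")) -> list[SampleMeta]:
    """2-strain x 2-diet design with ``n_per_group`` samples per cell."""
    metas = []
    for strain in strains:
        for diet in ("plant_oil", "fish_oil"):
            for i in range(n_per_group):
                metas.append(
                    SampleMeta(f"{strain}_{diet}_{i + 1}", strain, diet, tank=str(i % 3 + 1))
                )
    return metas


def simulate_counts(
    n_genes: int,
    meta: Sequence[SampleMeta],
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    de_fraction: float = 0.0,
    planted_log2fc: float = 0.0,
    phenotype_model: PhenotypeModel | None = None,
    seed: int = 0,
    de_group: Callable[[SampleMeta], bool] | None = None,
    gene_length_range: tuple[int, int] = (200, 10000),
) -> tuple[CountsMatrix, list[SampleMeta], SimTruth]:
    """NB count matrix with planted fold changes in a designated group.

    Counts are NB with variance mu + dispersion * mu^2. ``de_fraction`` of
    genes carry ``planted_log2fc`` in the samples selected by ``de_group``
    (default: every non-WT strain). Returns the counts, the metadata
    (phenotype filled in when a model is given) and the truth table.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    groups: dict[tuple[str, str], int] = {}
    for m in meta:
        groups[(m.strain, m.diet)] = groups.get((m.strain, m.diet), 0) + 1
    if any(n < 2 for n in groups.values()):
        raise ValueError("every (strain, diet) group needs at least 2 samples")

    if de_group is None:
        de_group = lambda m: m.strain != "WT"  # noqa: E731
    rng = np.random.default_rng(seed)
    n_samples = len(meta)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]

    n_de = int(round(de_fraction * n_genes))
    de_idx = np.sort(rng.choice(n_genes, size=n_de, replace=False)) if n_de else np.array([], dtype=int)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = planted_log2fc
    in_group = np.array([de_group(m) for m in meta])

    out_meta = list(meta)
    pheno = None
    slope_per_gene = np.zeros(n_genes)
    if phenotype_model is not None:
        pm = phenotype_model
        pheno = np.array(
            [
                pm.base
                + (pm.strain_delta if m.strain != "WT" else 0.0)
                + (pm.diet_delta if m.diet == "plant_oil" else 0.0)
                for m in meta
            ]
        ) + rng.normal(0.0, pm.sd, size=n_samples)
        out_meta = [
            SampleMeta(m.sample_id, m.strain, m.diet, m.tank, float(p))
            for m, p in zip(meta, pheno)
        ]
        if pm.n_correlated:
            corr_idx = rng.choice(n_genes, size=pm.n_correlated, replace=False)
            slope_per_gene[corr_idx] = pm.slope

    log2_mu = np.log2(baseline_mean) + np.outer(lfc, in_group.astype(float))
    if pheno is not None and slope_per_gene.any():
        z = (pheno - pheno.mean()) / max(pheno.std(), 1e-12)
        log2_mu = log2_mu + np.outer(slope_per_gene, z)
    mu = np.power(2.0, log2_mu)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_genes)
    cm = CountsMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                     columns=[m.sample_id for m in meta]),
        pd.Series(lengths, index=gene_ids, name="length"),
    )
    truth = SimTruth(
        scenario="counts_2x2",
        params={
            "n_genes": n_genes,
            "baseline_mean": baseline_mean,
            "dispersion": dispersion,
            "de_fraction": de_fraction,
            "planted_log2fc": planted_log2fc,
            "seed": seed,
            "phenotype": {m.sample_id: m.phenotype for m in out_meta},
        },
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "is_de": lfc != 0.0,
                "log2fc": lfc,
                "phenotype_slope": slope_per_gene,
            }
        ),
    )
    return cm, out_meta, truth
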