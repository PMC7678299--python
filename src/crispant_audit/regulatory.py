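"""Promoter extraction and position-weight-matrix scanning.

Promoter windows run from 1000 bp upstream to 200 bp downstream of the
annotated transcription start site. Windows are scanned on both strands with
log-odds (bits) scores against a background base composition; genes are
flagged when any supplied motif (for example an SRE-like Srebp binding
matrix) scores at or above the threshold in any transcript's window.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .genome import GenomicInterval, TranscriptModel, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PWM:
    motif_id: str
    probs: np.ndarray  # length x 4, rows sum to 1
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        bg = self.background if self.background is not None else np.full(4, 0.25)
        bg = np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be a position x 4 matrix")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, pseudocount: float = 1e-3) -> np.ndarray:
        """Per-position log2 odds with a pseudocount re-normalized in."""
        p = self.probs + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])

    def max_score(self, pseudocount: float = 1e-3) -> float:
        # sequential sum, matching the position-by-position accumulation in
        # pwm_scan, so the consensus sequence scores max_score bit-exactly
        return float(sum(self.log_odds(pseudocount).max(axis=1)))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, p: float = 0.997) -> "PWM":
        """One-hot-like PWM giving probability ``p`` to each consensus base."""
        probs = np.full((len(consensus), 4), (1 - p) / 3)
        for i, b in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[b]] = p
        return cls(motif_id, probs)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    offset: int  # 0-based within the promoter window (forward orientation)
    strand: str
    score: float  # log-odds bits


def read_jaspar_pwms(path: str | Path) -> list[PWM]:
    """Read JASPAR-format count/frequency matrices into PWMs."""
    pwms = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float).T
            totals = counts.sum(axis=1, keepdims=True)
            pwms.append(PWM(m.matrix_id or m.name, counts / totals))
    return pwms


def promoter_window(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    upstream: int = 1000,
    downstream: int = 200,
) -> str:
    """Promoter sequence around the TSS, in promoter (5'->3') orientation.

    Plus strand: [TSS - upstream, TSS + downstream). Minus strand: the
    reverse complement of the mirrored window. Windows are truncated at
    contig ends with a warning.
    """
    seq = str(genome[transcript.chrom])
    tss = transcript.tss
    if transcript.strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream + 1, tss + upstream + 1
    clipped_lo, clipped_hi = max(0, lo), min(len(seq), hi)
    if clipped_lo != lo or clipped_hi != hi:
        warnings.warn(
            f"promoter window of {transcript.transcript_id} truncated at contig end",
            stacklevel=2,
        )
    window = seq[clipped_lo:clipped_hi]
    return reverse_complement(window) if transcript.strand == "-" else window


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        idx[arr == ord(b)] = i
    return idx


def pwm_scan(
    seq: str,
    pwm: PWM,
    threshold: float,
    gene_id: str = "",
    pseudocount: float = 1e-3,
) -> list[MotifHit]:
    """All offsets (both strands) scoring >= threshold in bits.

    N (or other ambiguous) bases contribute 0 bits. Minus-strand hits are
    reported at the forward-orientation offset of the matched window.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    m = len(pwm)
    L = len(seq)
    if L < m:
        return []
    lo = pwm.log_odds(pseudocount)

    def scores_of(s: str) -> np.ndarray:
        idx = _encode(s)
        n = len(s) - m + 1
        out = np.zeros(n)
        for i in range(m):
            col = idx[i : i + n]
            contrib = np.where(col >= 0, lo[i, np.clip(col, 0, 3)], 0.0)
            out += contrib
        return out

    hits: list[MotifHit] = []
    fwd = scores_of(seq)
    for o in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(gene_id, pwm.motif_id, int(o), "+", float(fwd[o])))
    rev = scores_of(reverse_complement(seq))
    for o in np.flatnonzero(rev >= threshold):
        hits.append(MotifHit(gene_id, pwm.motif_id, int(L - m - o), "-", float(rev[o])))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def genes_with_motif(
    genes: Mapping[str, Sequence[TranscriptModel]],
    genome: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold: float,
    upstream: int = 1000,
    downstream: int = 200,
) -> tuple[set[str], pd.DataFrame]:
    """Genes with >= 1 motif hit in any transcript's promoter window.

    Returns the flagged gene set and the full per-hit table (gene_id,
    transcript_id, motif_id, offset, strand, score).
    """
    rows = []
    flagged: set[str] = set()
    for gid, transcripts in genes.items():
        for t in transcripts:
            window = promoter_window(t, genome, upstream, downstream)
            for pwm in pwms:
                for h in pwm_scan(window, pwm, threshold, gene_id=gid):
                    flagged.add(gid)
                    rows.append(
                        {
                            "gene_id": gid,
                            "transcript_id": t.transcript_id,
                            "motif_id": h.motif_id,
                            "offset": h.offset,
                            "strand": h.strand,
                            "score": h.score,
                        }
                    )
    table = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "motif_id", "offset", "strand", "score"]
    )
    return flagged, table
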