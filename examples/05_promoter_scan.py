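"""Scan gene promoters for an SRE-like motif.

Plants the sterol-regulatory-element-like consensus TCACCCCAC in the
promoters of a subset of toy genes and recovers exactly those genes with a
position-weight-matrix scan of the [-1000, +200) window around each TSS.
"""
from crispant_audit import (
    GenomicInterval,
    PWM,
    TranscriptModel,
    genes_with_motif,
)
from crispant_audit.simulate import random_dna

MOTIF = "TCACCCCAC"
chrom = "chr_toy"
seq = random_dna(40000, seed=36)

genes = {}
planted = set()
for i in range(10):
    gid = f"gene{i}"
    tss = 2000 + 3500 * i
    genes[gid] = [TranscriptModel(
        gid + "_t", gid, (GenomicInterval(chrom, tss, tss + 300),), (), "+",
    )]
    if i % 3 == 0:  # plant the motif 250 bp upstream of every third TSS
        seq = seq[: tss - 250] + MOTIF + seq[tss - 250 + len(MOTIF):]
        planted.add(gid)

pwm = PWM.from_consensus("SRE_like", MOTIF)
threshold = pwm.max_score() - 0.5
flagged, hits = genes_with_motif(genes, {chrom: seq}, [pwm], threshold)

print(f"planted in: {sorted(planted)}")
print(f"flagged:    {sorted(flagged)}")
assert flagged == planted
print("\nhit table:")
print(hits.to_string(index=False))
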