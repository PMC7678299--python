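"""Profile CRISPR mosaicism at a target site from simulated amplicon reads.

A founder ("crispant") fish carries a mix of indel alleles at each gRNA cut
site. This example simulates 2,000 amplicon reads from a 60/30/10 allele
spectrum, computes the per-base indel proportion in the 25 bp window around
the cut, tallies alleles, and classifies each allele's predicted impact on a
small coding transcript spanning the site.
"""
from crispant_audit import (
    AlleleSpectrum,
    GenomicInterval,
    IndelEvent,
    TargetSite,
    TranscriptModel,
    classify_impact,
    impact_composition,
    indel_profile,
    simulate_mosaic_amplicons,
    tally_alleles,
)
from crispant_audit.simulate import random_dna

# a 600 bp amplicon with the Cas9 cut at offset 300
reference = random_dna(600, seed=97)
site = TargetSite("gRNA1", reference[283:303], "AGG", "amplicon", 300, "+")

spectrum = AlleleSpectrum((
    ((IndelEvent("deletion", 299, 2),), 0.6),     # 2 bp deletion -> frameshift
    ((IndelEvent("insertion", 299, 1, "A"),), 0.3),  # 1 bp insertion -> frameshift
    ((), 0.1),                                     # unedited
))
reads, truth = simulate_mosaic_amplicons(reference, site, spectrum,
                                         n_reads=2000, seed=1)

profile = indel_profile(reads, site)
print(f"max indel proportion in the cut window: {profile.max_proportion:.3f}")

alleles, excluded = tally_alleles(reads, site.window(25))
print(f"{len(alleles)} alleles; {excluded} partial reads excluded")
for a in alleles:
    print(f"  {a.allele_signature:<12} {a.read_count:>5} reads")

# classify each allele against a coding transcript covering the amplicon
transcript = TranscriptModel(
    "t1", "g1",
    exons=(GenomicInterval("amplicon", 50, 550),),
    cds=(GenomicInterval("amplicon", 90, 540),),
)
calls = {
    a.allele_signature: classify_impact(a.events, transcript, {"amplicon": reference})
    for a in alleles
}
comp = impact_composition(alleles, calls, sample_id="founder_1")
print("impact composition (read-weighted):")
for category, fraction in comp.fractions.items():
    print(f"  {category:<9} {fraction:.3f}")
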