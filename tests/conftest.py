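"""Shared fixtures: toy annotations, genes and references."""
from __future__ import annotations

import pytest
from hypothesis import settings

from crispant_audit import (
    GenomicInterval,
    TranscriptModel,
    make_exon_skip_gene,
)

# deterministic, CI-friendly hypothesis profile (no deadline flakiness)
settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


TOY_GFF3 = """##gff-version 3
##sequence-region chr1 1 10000
chr1\t.\tgene\t101\t1000\t.\t+\t.\tID=gene1
chr1\t.\tmRNA\t101\t1000\t.\t+\t.\tID=tx1;Parent=gene1
chr1\t.\texon\t101\t200\t.\t+\t.\tParent=tx1
chr1\t.\texon\t301\t400\t.\t+\t.\tParent=tx1
chr1\t.\texon\t501\t1000\t.\t+\t.\tParent=tx1
chr1\t.\tCDS\t151\t200\t.\t+\t.\tParent=tx1
chr1\t.\tCDS\t301\t400\t.\t+\t.\tParent=tx1
chr1\t.\tCDS\t501\t600\t.\t+\t.\tParent=tx1
chr1\t.\tmRNA\t101\t400\t.\t+\t.\tID=tx2;Parent=gene1
chr1\t.\texon\t101\t200\t.\t+\t.\tParent=tx2
chr1\t.\texon\t301\t400\t.\t+\t.\tParent=tx2
"""


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(
        'chr1\ttest\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
        'chr1\ttest\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\ttest\texon\t101\t150\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\ttest\texon\t171\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    )
    return path


@pytest.fixture
def skip_gene():
    """Toy three-exon gene: (inclusion isoform, skip isoform, skippable part)."""
    return make_exon_skip_gene()


@pytest.fixture
def coding_transcript():
    """Single-chromosome multi-exon coding transcript for impact tests.

    Exons [100,200), [300,400), [500,700); CDS [150,200), [300,400), [500,600).
    """
    c = "chr1"
    return TranscriptModel(
        "tx1",
        "gene1",
        (
            GenomicInterval(c, 100, 200),
            GenomicInterval(c, 300, 400),
            GenomicInterval(c, 500, 700),
        ),
        (
            GenomicInterval(c, 150, 200),
            GenomicInterval(c, 300, 400),
            GenomicInterval(c, 500, 600),
        ),
        "+",
    )
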