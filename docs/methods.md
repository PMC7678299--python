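# Methods

Models, parameter defaults and numerical choices, with the rationale for
each. Everything here is implemented in `src/crispant_audit/` and pinned by
the test suite.

## Coordinates and gene models

All internal coordinates are 0-based half-open on the forward strand;
conversion from the 1-based inclusive GFF3/GTF convention happens only in
`read_gene_models` / `write_gene_models` (backed by `gffutils`). Orphan
exons (no parent transcript) are a structural error, not silently dropped.
A gene's **exonic parts** are the minimal fragments obtained by cutting the
exon union at every transcript exon boundary, numbered 1..n in genomic-start
order regardless of strand so a part index names the same genomic fragment
in every transcript. The **main transcript** of a gene is the one with the
longest CDS (ties broken lexicographically by transcript id) — a common,
deterministic convention when the annotation does not mark a canonical
isoform.

## Target sites and the cut position

A gRNA query is a 23-nt protospacer + NGG PAM, matched exactly on both
strands. Cas9 cuts bluntly 3 bp 5′ of the PAM, so a plus-strand match
starting at offset `o` puts the cut position (first base 3′ of the cut) at
`o + 17`; a minus-strand match (the query's reverse complement found on the
forward strand, PAM-complement leading) puts it at `o + 5`. All matches are
returned, because a single gRNA can target multiple loci (e.g. duplicated
genes in salmonids).

## Mosaicism profiling

* **Window** = 25 bp centred on the cut (default): wide enough to capture
  the indel spectrum around the cut while excluding unrelated variation;
  must be odd so the cut base is centred.
* **Per-base proportion** = reads with a deletion spanning the base or an
  insertion anchored at it, divided by reads whose alignment covers the base
  (M/=/X/D consume; N gaps do not). Bases with coverage below
  `min_coverage = 50` report NaN and are excluded from `max_proportion`,
  avoiding noisy proportions at window edges. `min_mapq = 20` drops
  ambiguous alignments; secondary/supplementary records are ignored.
* **Insertion anchoring**: an insertion between reference bases `p` and
  `p+1` is recorded at anchor `p` (the 5′ base). For allele tallying an
  insertion anchored at the base immediately 5′ of the window is treated as
  inside it, so a cut-site insertion is never lost to an off-by-one.
* **Alleles** are canonical serializations of a read's in-window events,
  ordered by reference position (`ins@295:GG;del@310:1`); the empty allele
  is `WT`. Only reads covering the full window are tallied (partial reads
  cannot distinguish WT from unobserved edits) and the excluded count is
  reported.
* **Impact classification**, in priority order: no indel → WT; any event
  within 2 nt of an internal exon boundary → HIGH/splice_site (the
  canonical splice dinucleotides); net CDS length change not divisible by
  3 → HIGH/frameshift; a new in-frame stop in the reconstructed CDS →
  HIGH/stop_gained (requires the reference sequence; without it the allele
  falls through to the next rule); other CDS-overlapping alleles →
  MODERATE/inframe_indel; UTR/intron-only → LOW/noncoding. This mirrors the
  common variant-effect convention (splice > frame > stop > in-frame).
* **Composition** is read-weighted (each read votes with its allele's
  category), reflecting the mosaic cell population rather than the allele
  catalogue.

## Exon retention (PER)

For one exonic part, a read supports **inclusion** when ≥ `min_anchor = 6`
aligned bases fall inside the part, and **exclusion** when a spliced N-gap
fully covers the part and the flanking aligned blocks each overlap the
gene's exonic sequence by ≥ `min_anchor`. A gap that only partially overlaps
the part is **ambiguous** and counts in neither class. A read can never be
both (a gap covering the part leaves no aligned bases in it); the code
asserts this. PER = 100·I/(I+E), undefined (None) with no informative
reads. `min_anchor = 6` is a standard junction-anchor length: long enough
that random alignment overhangs rarely fake a junction, short enough to keep
most junction reads.

**Toy gene geometry** (`make_exon_skip_gene`): flanking exons of 44 nt, a
66 nt skippable part, 80 nt introns, 50 nt reads. The skip isoform is then
88 nt = 2·read_len − 2·min_anchor, so *every* fragment from either isoform
is informative (no fragment can sit entirely in one flanking exon or anchor
too weakly), making the expected PER exactly 100 × the inclusion level —
which is what lets the simulator serve as an unbiased oracle.

**Skip consequence**: the removed CDS length is the part's overlap with the
transcript's CDS; skipping is in frame iff that length is divisible by 3
and (when a reference is supplied) the fused junction introduces no stop
codon; in-frame skipping removes length/3 amino acids.

## Expression analytics

* **CPM** = count · 10⁶ / library size; **TPM** length-normalizes first and
  rescales so each sample sums to 10⁶. **Filter**: keep genes with
  ≥ 1 CPM in at least ⌈0.75 · n⌉ samples (defaults configurable).
* **NB differential expression**: two-group likelihood-ratio test with
  variance μ + φμ². Group means are 1-parameter NB intercept MLEs
  (vectorized Newton on log μ, fixed φ, clipped steps); the alternative is
  the sum of per-group fits, the null a single fit; p = χ²₁ upper tail of
  the LRT. log2FC = log2((mean_B + 0.5)/(mean_A + 0.5)) on scaled counts.
  All-zero genes get p = 1, log2FC = 0.
* **Size factors**: median-of-ratios, computed after trimming the 15% of
  genes at each tail of the between-group log-ratio. Raw library-size
  offsets are biased when differential expression is one-directional
  (composition bias shifts every null gene's fold change); plain
  median-of-ratios reduces but does not remove the bias at 10% planted DE.
  The trim is shift-invariant, so no prior normalization is needed.
* **Dispersion**: per-gene method-of-moments on size-factor-scaled counts
  (pooled within-group variance, with the Poisson part inflated by
  mean(1/s) to account for the scaling), floored at 1e-4 and capped at 20,
  then shrunk on the log scale with weight 0.9 toward a trend fitted as a
  running mean over log-mean bins. The strong shrinkage reflects the small
  per-group sample size (n = 6): per-gene moment estimates are very noisy
  and under-dispersion artifacts inflate false positives. The weight was
  chosen by sweeping {0.7, 0.8, 0.9, 1.0} against the type-I-error and
  false-discovery calibration targets on seeds disjoint from those used in
  tests; 0.9 centres both.
* **BH-FDR** is the standard step-up procedure (own implementation,
  cross-checked against enumeration and statsmodels). DEG = q < 0.05 and
  |log2FC| > 0.5.
* **Enrichment**: hypergeometric upper tail P(X ≥ k) with N = universe,
  K = pathway∩universe, n = DEGs, k = overlap; significant at p < 0.005.
* **PCA**: log2(CPM + 1), top 1000 most variant genes (ties broken by
  gene id for determinism), rows centred but not scaled, SVD;
  variance explained = 100·σᵢ²/Σσ². Scores are reported per sample.
* **Phenotype correlation**: Pearson r with the exact two-sided t-test
  (n − 2 df); constant vectors are reported as undefined with reason
  `zero_variance` rather than r = NaN.

## Promoter motif scanning

Promoter window = [TSS − 1000, TSS + 200) in promoter orientation (minus
strand: reverse complement of the mirrored window), truncated with a warning
at contig ends. Scores are log2-odds bits against a uniform background with
pseudocount 1e-3 renormalized into the probabilities (avoids −∞);
N bases contribute 0 bits. Both strands are scanned; minus-strand hits are
reported at the forward-orientation offset. A gene is flagged when any
transcript's window has ≥ 1 hit from any PWM — the gene-level convention
when multi-TSS handling is unspecified. JASPAR-format matrices are read via
Biopython. The bits threshold is a free parameter: no claim is made about
any particular database's match criterion.

## Simulators

All generators are pure functions of their arguments including the seed.

* **Amplicons**: alleles drawn multinomially from the spectrum; read start
  uniform over the positions from which the read still covers the full
  window given the allele's net indel length; CIGAR built by walking the
  reference. Substitution errors (optional) hit only M-aligned query
  positions — never inserted bases — so the per-read allele truth stays
  unambiguous by construction.
* **Spliced reads**: fragment from the inclusion isoform with probability
  `inclusion_level`, else from the skip isoform; uniform start along the
  chosen isoform; projected to genomic coordinates with N gaps at introns
  and at the skipped part. Single-end only.
* **Counts**: NB(μ, φ) with variance μ + φμ² via
  `rng.negative_binomial(r, r/(r+μ))`, r = 1/φ; a 2-strain × 2-diet design
  with ≥ 2 samples per cell; `de_fraction` of genes carry `planted_log2fc`
  in the designated group (default: non-WT strains); optional DHA-like
  phenotype covariate (group shifts + Gaussian noise) with a chosen set of
  genes whose log2 expression tracks the phenotype z-score.

Not modelled: sequencing error profiles, GC/positional bias, paired ends,
indel sequencing errors, fastq-level simulation (alignments are generated
directly).

## Vocabulary

Strains: `WT`, `d6abc5_mt` (delta-6 fads2 a/b/c + delta-5 knockout-like),
`d6bc_mt` (delta-6 fads2 b/c); diets: `plant_oil`, `fish_oil`. ASCII-only
tokens keep TSV outputs and CLI arguments shell-safe.

## Limitations

* Impact classification scores one (main) transcript per gene; per-isoform
  audits require calling `classify_impact` per transcript.
* The DE test is two-group only; interaction effects in the 2×2 design are
  assessed by running the four pairwise contrasts, not a joint GLM.
* Enrichment treats genes as exchangeable (no length or expression bias
  correction).
* PER assumes single-end reads and one skippable part at a time;
  overlapping alternative events are not deconvolved.
* The trimmed-ratio size factors assume < ~70% of genes are differentially
  expressed in one direction; beyond that, no global normalization is
  identifiable without spike-ins.
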