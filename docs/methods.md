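# Methods

## Deletion scar model

A deletion replaces the body of a target gene while retaining its first codon
and its last seven codons (six amino-acid codons plus the stop; kept in case
they harbor a ribosome-binding site for a downstream gene). Two scar forms
are modeled:

| component        | length | bar scar | erm-bar scar |
|------------------|-------:|:--------:|:------------:|
| start codon ATG  |      3 | ✓        | ✓            |
| left linker (LL) |     32 | ✓        | ✓            |
| FRT remnant      |     34 | ✓        | — (cassette) |
| FRT-erm-FRT      |    948 | —        | ✓            |
| spacer           |     18 | ✓        | ✓            |
| barcode          |     18 | ✓        | ✓            |
| right linker (RL)|     33 | ✓        | ✓            |

The *bar* scar totals 138 bp. The scar is modeled as *including* the start
codon: 3 + 32 + 34 + 18 + 18 + 33 is the only decomposition of 138 consistent
with the printed component sequences, so the scar's ATG is the gene's own
start codon and `apply_deletion` splices `scar[3:]` after it. The barcode
begins at offset 87 — a codon boundary — so it occupies whole codons 29–34 of
the scar and contributes no frame shift.

**FRT remnant.** The post-excision FRT sequence is not fixed by the printed
components, so the package uses the canonical 34-nt minimal FRT site
(13-bp repeat + 8-bp core + 13-bp inverted repeat,
`GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC`); 34 nt is the unique length that makes
the component sizes sum to 138 bp, and this sequence keeps the assembled scar
free of in-frame stops for every valid barcode (asserted in tests). It is a
configurable field of `LinkerSet` for users whose construct differs.

**erm cassette.** The cassette interior is a deterministic pseudorandom
synthetic placeholder (FRT + 880 nt + FRT = 948 nt), sized so the marked
middle fragment LL–cassette–spacer–barcode–RL is 1,049 bp. It stands in for a
real resistance cassette only structurally: FLP excision is modeled as
replacing the whole FRT-…-FRT interval with one FRT remnant, and tests assert
this reproduces the *bar* scar exactly.

## Barcodes

Barcodes are six trimers sampled uniformly from the 48 VNN codons
(V = A/C/G, N = any). Because all three stop codons begin with T, no
trimer-aligned stop can occur; the equivalent degenerate segment on the
reverse construction primer is six NNB trimers. The library builder
rejection-samples until barcodes are unique and pairwise Hamming distance
≥ `min_distance` (default 3, so any single sequencing substitution cannot
convert one library barcode into another; 0 is accepted for designs that
impose no floor). Ambiguity codes are rejected in concrete barcodes.

## Oligo design

Eight oligos per target, all positioned by fixed offsets (no melting-
temperature optimization; anneal length default 22 nt, bounds 18–30):

- F1 / R2 anneal starting 1 kb upstream/downstream of the gene.
- R1-LL anneals ending at the start codon and carries the 32-nt reverse
  complement of LL; F2-RL anneals from the last seven codons downstream and
  carries RL.
- FO / RO sit 500 bp outside F1 / R2 for junction screening.
- FW / RW amplify an internal fragment of 500–1,000 bp on the wild-type
  template whose absence confirms the deletion; genes whose internal span
  (length − 24) is under 500 bp fall back to the full span with a warning.

Minus-strand genes are designed on the coding orientation and anneal
intervals are mapped back to forward-strand coordinates. Coordinates are
0-based half-open internally and 1-based inclusive in all user-facing tables.

SOE joining (`soe_join`) fuses fragments at their unique terminal overlap
≥ `min_overlap` (default 15 nt); no overlap or multiple candidate overlap
lengths raise errors naming the junction, since either would make the PCR
product ambiguous.

## Competition and read simulation

Growth is deterministic exponential: output frequency ∝ input × fitnessᵍ,
renormalized. This is the simplest model sufficient for parameter-recovery
testing — the competitive index under it is exactly g·log₁₀(w) for a mutant
with fitness w against neutral references. An optional bottleneck is a single
seeded multinomial draw, emulating the stochastic founding of a host-
associated population. The simulator does **not** model PCR amplification
bias, chimeras, index hopping, PhiX, paired-end overlap, or indels (a
substitution-only error model is applied i.i.d. per base), so passing tests
demonstrate correctness of the accounting and arithmetic, not robustness to
every artifact of real MiSeq data.

Amplicons follow the dual-indexed layout P5–i5–head–scar–tail–i7′–P7′; with
8-nt indexes and 12-nt synthetic head/tail placeholders the template is
231 bp. Reads are the first `read_length` nt of the template (default 250,
minimum 54 = spacer + barcode + right flank), a seeded fraction optionally
reverse-complemented, with constant placeholder qualities (quality is unused
downstream). Identical scenario + seed gives byte-identical FASTQ.

## Counting

Extraction searches each read for the literal left flank (18-nt spacer),
exactly 18 candidate nucleotides, and the literal right flank (first 18 nt of
RL). Defaults: exact flank matching (`max_flank_mismatches = 0`, matching the
literal-pattern description of the original tool) with a configurable
per-flank substitution tolerance for error-containing data, and both-strand
search ON (250-nt reads can present the locus in either orientation). The
first matching window wins; reads are never double-counted. Candidates
containing N go to `_other`. Per-sample conservation — matched + `_other` =
reads-with-flanks ≤ total reads — is enforced by the `CountsTable` container
and asserted against an independent tally in tests.

## Statistics

Relative frequency excludes `_other` from numerator and denominator by
default (it can be included for diagnostics). The wild-type reference is the
arithmetic mean RF over the named WT strains; WT strains also receive CIs
against their own mean, serving as internal controls. Technical replicates
are summed (count-level pooling), not averaged, before RF computation.

Zero counts: a strain with zero reads in the input or an output sample gets
its CI computed at a 0.5-read pseudocount and is flagged `censored` (the
reported value is a detection floor, not an estimate); `zero_policy=
"pseudocount"` reports the same number unflagged. No hypothesis testing is
built in; multiple output samples are reported per sample and summarized at
the reporting layer.

The qPCR polarity ratio uses the 2^−ΔΔCt method with a reference gene
(default `rpoD`): rel(g,s) = 2^−(Ct(g,s)−Ct(ref,s)), fold(g) =
rel(g,mut)/rel(g,wt), and the ratio is fold(downstream)/fold(upstream).
Repeated (strain, gene) rows are averaged as technical replicates. A ratio
near 1 indicates a non-polar deletion.

## Problem sizes and tolerances

The test suite exercises 10⁵ barcode draws for the stop-codon and
uniformity properties (uniformity band: 1/48 ± 5 s.e.), 200 random SOE
reconstructions, 1,000 random count tables against a one-line CI oracle at
1e-12, and an end-to-end recovery run with 7 strains × 5×10⁴ reads per
sample. Monte-Carlo bounds for CI recovery use the delta method on
multinomial counts (variance of a sample's log₁₀ RF-ratio term:
[(1−f_m)/(N·f_m) + (1−F_w)/(N·F_w) + 2/N] / ln²10, summed over input and
output samples); recovered CIs must fall within 3 such s.d. of g·log₁₀(w),
and neutral strains within |CI| < 0.05.

## Known limitations

- The FRT remnant and erm-cassette interior are structural placeholders;
  sequence-level fidelity to any particular plasmid is out of scope.
- Primer thermodynamics and off-target screening are not modeled; oligo
  positions are purely offset-based.
- The detection floor is the pseudocount CI, not an experiment-level limit
  of detection, which depends on read depth and library composition and is
  left to the user as a reporting threshold.
- Demultiplexing by i5/i7 is assumed done upstream; the counter consumes
  per-sample FASTQ files named in an explicit sample sheet.
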