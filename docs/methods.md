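# Methods

This note documents the model behind each stage, the defaults that matter,
the design choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish about real data.

## Candidate generation

**Missense windows.** MHC class I ligands are canonically nonamers, so a
substitution at protein position *p* is covered by the tiling windows whose
1-based starts run from max(1, *p*−8) to min(*p*, *L*−8). Interior mutations
give exactly nine windows; mutations within eight residues of a terminus give
fewer and are reported as such — padding would fabricate sequence, so none is
done. Each mutant window is paired with the wild-type window at the same
offset; the pair differs at exactly one position, which is asserted as an
invariant. The window length *k* is configurable (default 9) to allow 8–11-mer
extensions, but all shipped defaults and fixtures use 9. Windows containing a
residue outside the 20-letter alphabet (e.g. `X`) are generated but flagged
non-scorable, since binding matrices cover only the standard residues.

A reference-residue mismatch between the variant annotation and the supplied
protein raises an error reporting expected vs found; this deliberately
surfaces transcript-version drift instead of silently mutating the wrong
residue.

**Fusion junctions.** The module consumes assembled breakpoints (fusion
detection and junction-read assembly are upstream concerns): `n5` retained
coding nucleotides of the 5′ partner and the coding offset `n3off` of the 3′
breakpoint. The chimera preserves the 3′ partner's native register iff
(n5 − n3off) mod 3 = 0; out-of-frame events yield no candidates by default
(a frameshifted 3′ tail is biologically a different peptide space and is out
of scope; the junction builder itself accepts any offsets). Translation uses
the standard code, stops at the first stop codon, drops a trailing partial
codon, and renders codons containing non-ACGT bases as `X`.

A breakpoint that splits a codon produces a chimeric codon whose residue is
assigned to *both* sides for window-overlap purposes — it is sequence-novel by
construction. Junction windows are then exactly the k-mers that are neither
wholly 5′ nor wholly 3′ of the break; the test suite checks this against a
set-algebra enumeration. Breakpoints retaining no 5′ coding sequence, or
followed immediately by a stop codon, yield zero candidates with a logged
reason rather than an error.

## Binding prediction

Affinity prediction is a contract (`peptide, allele -> IC50 nM`) with two
implementations:

* a **table adapter** for whitespace-delimited output of an external
  predictor (allele spellings are normalized, decoration lines skipped, the
  affinity taken from the last numeric field after the peptide/allele
  columns);
* a **matrix scorer** used by all tests: per-allele 9 × 20 position weight
  matrices with weights in [0, 1]; a peptide's normalized score *s* is the
  mean of its per-position weights, mapped to nM via IC50 = 50000^(1−*s*) —
  the standard transform between normalized predictor scores and affinities.

The selection rule keeps IC50 ≤ 500 nM, *inclusive*, the conventional
moderate-to-high-affinity cutoff. No percentile-rank filtering is applied.
Each unique (peptide, allele) pair is scored once per sample — a homozygous
locus does not double-score — but candidates are never collapsed across
alleles or registers before reporting, because one mutation can legitimately
yield several epitopes in different registers or on different alleles.
Deduplication to distinct (sample, peptide, allele) happens only in the
reporting counts. Alleles a backend cannot score are logged and skipped,
never silently scored.

## Expression evidence

The strict rule: a candidate window is expressed iff at least one RNA-seq
read **both** carries the mutant allele at the variant position **and** spans
all 27 genomic bases encoding the nonamer within its aligned match blocks.
The spanning read must itself support the mutant allele because only then is
the evidence tied to the mutant peptide rather than the wild-type transcript;
a config flag (`strict_mutant_spanning: false`) relaxes this to any spanning
read for sensitivity analysis.

The 27-base requirement is evaluated per window, so one mutation can have
some registers expressed and others not. Splice gaps (CIGAR `N`) between
match blocks do not break spanning — they are transcript-consistent — but a
deletion (`D`) overlapping any window base does. Codon coordinates honour
exon structure and strand, so windows may map to split genomic runs and
minus-strand windows descend genomically.

Read filters: duplicate-marked, secondary and supplementary alignments are
excluded; defaults of mapping quality ≥ 1 and base quality ≥ 20 at the
variant position are config-exposed (`min_mapq`, `min_base_quality`) and
logged. Fusion candidates are evaluated on the junction contig, where the
window at peptide offset *w* occupies contig bases 3*w* .. 3*w*+27 and any
spanning read evidences the fusion product (the junction itself is the
somatic lesion, so a mutant-allele test is vacuous).

Samples without RNA-seq get expression state `unknown` for every candidate,
never `no`; per-sample expressed counts are null, not zero.

## HLA concordance

Scoring is at two-field resolution (higher resolution is truncated with a
warning). Per locus: heterozygous truth is scored by maximum bipartite
matching between truth and called pairs (each called allele credits at most
one truth allele; order-independent); homozygous truth scores 2 iff called
homozygous for that allele, 1 iff called heterozygous with one matching
allele, else 0. The truth-heterozygous / called-homozygous case is not fully
pinned down by the scoring convention's usual statement; the matching rule
adopted here gives 1 when the called allele matches either truth allele,
which is the natural no-double-counting choice. Cohort accuracy is
100 × Σ correct / (2 × loci), rounded half-up to one decimal. Carrier
frequencies count a sample once per allele regardless of zygosity.

## Reporting conventions

Percentages are rounded half-up at one decimal (proportions of magnitude
≤ 1 at two decimals; per-subtype means at two decimals). "Number of
neoepitopes" is ambiguous between mutations-with-≥1-passing-candidate and
peptide–allele pair counts; both are emitted (`n_neoepitope_mutations`,
`n_candidates`) so downstream consumers need not guess. Relapse samples are
excluded from primary subtype averages and reported in companion
`*_with_relapse` columns. The regression of candidate count on mutation count
is ordinary least squares; a constant response is reported as R² = 0.

Published cohort figures contain a few internal inconsistencies (e.g. a
fusion-positive proportion quoted both as 69.6% and as 68% (32/47); a carrier
count of 105/540 printed as 19.6% where the quotient is 19.4%). The reporting
module computes each fraction from its printed numerator and denominator
as-is and takes no side.

## Synthetic fixtures

The simulator emulates, deterministically from a seed: a toy genome (one
chromosome per gene; 1–3 exons; both strands; 50 nt introns; 40–80 aa
proteins), somatic missense variants with reads placed to realise a chosen
expression state, in-frame and frameshifted fusions with junction contigs,
genotypes drawn from a pool of twelve common class I alleles, and binding
matrices built so a planted (peptide, allele) pair — and, by the 4-of-9 match
arithmetic, essentially only it — clears 500 nM. Planted truth (windows,
binders, expression flags, summary counts) is computed by independent
brute-force enumeration, not by the pipeline code under test, so end-to-end
equality is a genuine cross-check.

The default cohort (8 samples, 2–4 variants each, a fusion on every other
sample, 75% RNA availability, 70% of lesions planted as binders) is sized for
desk-scale runs; the acceptance script uses 12 samples. The embedded KRAS and
histone H3.1/H3.3 context fragments (30 and 40 residues, mature-protein
numbering for H3) anchor the field's worked examples without any database
fetch; their CDS are deterministic reverse-translations, so their genomic
coordinates are synthetic even though the peptide sequences are canonical.

What the fixtures do **not** model: sequencing error, coverage variation,
tumor purity and clonality, multi-transcript genes, UTRs, real binding-motif
structure, and realistic mutation rates. Passing the planted-truth check
therefore demonstrates the correctness of the combinatorics, arithmetic and
plumbing — not predictive accuracy on real tumors, which is inherited from
whatever external predictor is plugged in.

## Numerical choices and degenerate inputs

* Rounding is half-up (`decimal.ROUND_HALF_UP`) everywhere a printed-precision
  figure is produced; Python's bankers' rounding is never used for reported
  numbers.
* The IC50 threshold comparison is `<=`; the score-to-nM transform is exact
  (no clamping), with 50000 nM as the no-affinity ceiling.
* Sequences shorter than the window length yield empty window lists with a
  logged warning, not an error; a mutation position outside the protein is an
  error.
* Genomic coordinates are 0-based half-open internally; variant tables are
  1-based at the file boundary and converted exactly once on read. Protein
  positions are 1-based throughout. Coordinates are assumed to belong to a
  single stated assembly per run; no liftover is attempted.
* Ties in candidate ordering are broken by (sample, source, lesion, window
  offset, allele) so outputs are byte-reproducible.

## Known limitations

Indel/frameshift peptides, splice-variant peptides, class II 15-mers,
proteasomal-cleavage and TAP-transport modelling, immunogenicity prediction,
expression quantification (TPM/FPKM), HLA calling from reads, fusion
detection from reads, and haplotype/ancestry analysis are all out of scope.
Multi-allelic and symbolic variant records are not parsed; SAM text (not
BAM/CRAM) is the supported alignment input for fixtures, though the reader
goes through pysam and a BAM adapter would be a one-line extension.
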