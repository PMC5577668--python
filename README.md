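# neoscan

Neoepitope discovery for cancer cohorts: from somatic missense mutations and
expressed gene fusions, plus each patient's HLA class I genotype, to candidate
MHC-presented mutant peptides with RNA-seq expression evidence and cohort-level
landscape summaries.

## Who this is for

Cancer immunogenomics analysts who have, per tumor sample:

* somatic missense SNV calls annotated with amino-acid changes and read counts,
* gene-fusion breakpoints at transcript level (with retained-CDS arithmetic),
* two-field HLA class I calls (HLA-A/-B/-C, e.g. `HLA-A*02:01`),
* optionally RNA-seq alignments (SAM),

and want the candidate neoepitope repertoire of the cohort, reproducibly and
with every intermediate inspectable.

## The method

**Missense windows.** A substitution at protein position *p* can occupy any of
the nine registers of a 9-mer, so the mutant context *p* ± 8 yields up to nine
tiling nonamers (fewer near a terminus), each paired with its wild-type
counterpart, which differs at exactly one position.

**Fusion junctions.** With *n₅* coding nucleotides retained from the 5′
partner and the 3′ breakpoint at coding offset *n₃* of its own CDS, the chimera
keeps the 3′ partner's native codon register iff

&nbsp;&nbsp;&nbsp;&nbsp;(*n₅* − *n₃*) mod 3 = 0.

Only such in-frame junctions are translated (standard code, stop-truncated),
and only the nonamers overlapping the breakpoint — at least one residue
encoded on each side, a codon split by the break counting for both — are kept.

**Binding filter.** Each nonamer is scored against each of the sample's
distinct HLA class I alleles; candidates with predicted IC50 ≤ 500 nM
(inclusive; the conventional moderate-to-high-affinity cutoff) pass. Scoring
is a pluggable contract: an adapter for tabular output of an external
predictor, and a built-in deterministic position-weight-matrix scorer whose
normalized score *s* maps to nM via IC50 = 50000^(1−s).

**Expression evidence.** A candidate is *expressed* when at least one RNA-seq
read both carries the mutant allele and spans, within its aligned match
blocks, all 27 genomic bases encoding the nonamer (splice gaps allowed,
deletions not). Fusion candidates use reads aligned to the junction contig.
Samples without RNA-seq are reported `unknown`, never `no`.

**HLA concordance.** Sequencing-derived genotypes are scored against clinical
typing per locus: heterozygous truth by maximum matching (0–2 correct,
order-independent); homozygous truth scores 2 only when called homozygous for
that allele, 1 when called heterozygous with one match. Cohort accuracy is
100 × correct alleles / (2 × loci), one decimal, half-up.

**Reporting.** Per-sample counts (missense mutations, mutations with ≥ 1
passing candidate, distinct peptide–allele pairs, expressed pairs), per-subtype
means with relapse samples shown separately, recurrence tables per lesion,
cohort proportions (half-up rounding at printed precision), and an OLS
regression of epitope count on mutation burden.

## Worked example

Everything runs offline on generated fixtures:

```bash
neoscan simulate --seed 20170831 --out-dir fixtures/
cat > config.yaml <<'EOF'
proteins: fixtures/proteins.fasta
cds: fixtures/cds.fasta
transcripts: fixtures/transcripts.tsv
variants: fixtures/variants.tsv
fusions: fixtures/fusions.tsv
hla: fixtures/hla.tsv
reads: fixtures/reads.sam
contigs: fixtures/contigs.fasta
matrices: fixtures/matrices.tsv
samples: fixtures/samples.tsv
outdir: out/
EOF
neoscan run --config config.yaml
```

prints `56 candidates -> out`: the synthetic cohort of 8 samples carries 22
missense variants and 4 fusions, and the pipeline recovers exactly the 56
candidate records planted by the simulator (compare `out/candidates.tsv`
with `fixtures/truth.json`). The library surface is equally direct:

```python
>>> from neoscan import ProteinRecord, MissenseVariant, missense_candidates
>>> from neoscan.simulate import KRAS_CONTEXT
>>> kras = ProteinRecord("KRAS_P", "KRAS", KRAS_CONTEXT, mrna_accession="KRAS_T")
>>> v = MissenseVariant("S1", "chr12", 1, "C", "T", "KRAS", "KRAS_T", "G", 13, "D")
>>> [m for _, m, _ in missense_candidates(kras, v).windows][3]
'VVGAGDVGK'
```

— the well-known KRAS G13D epitope appears among the nine tiling nonamers.

## Layout

| module | responsibility |
|---|---|
| `neoscan.models` | domain types (variants, fusions, genotypes, candidates, reads) |
| `neoscan.io` | TSV/FASTA/SAM readers and writers |
| `neoscan.peptides` | mutant tiling-nonamer windows |
| `neoscan.fusion` | junction assembly, frame arithmetic, translation, windows |
| `neoscan.binding` | predictor contract, matrix scorer, IC50 filter |
| `neoscan.expression` | codon-to-genome mapping, 27-base span rule |
| `neoscan.concordance` | HLA typing accuracy and carrier frequencies |
| `neoscan.report` | per-sample/cohort summaries, recurrence, regression |
| `neoscan.simulate` | deterministic fixtures with planted ground truth |
| `neoscan.pipeline` / `neoscan.cli` | orchestration and the `neoscan` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
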