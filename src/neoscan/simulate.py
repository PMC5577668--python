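"""Deterministic synthetic fixtures with planted ground truth.

Every stage of the pipeline is testable offline: this module generates a toy
reference (multi-exon transcripts on both strands), somatic missense variants
with RNA-seq reads placed to make chosen windows expressed or not, in-frame
and frameshifted fusions with junction contigs and reads, HLA genotypes drawn
from a small pool of common class I alleles, and per-allele scoring matrices
constructed so that chosen (peptide, allele) pairs - and only those - pass
the 500 nM filter.  The planted truth (expected windows, binders, expression
flags and summary counts) is recorded alongside and is computed by
independent brute-force arithmetic, not by the pipeline under test.

All generators are pure functions of (seed, parameters); regenerating with
the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .binding import ScoringMatrix, write_matrices
from .errors import InfeasiblePlantError, ValidationError
from .fusion import _CODON_TO_AA, _STOPS, junction_contig_name, translate_cds
from .models import (
    RESIDUES,
    FusionEvent,
    HlaGenotype,
    MissenseVariant,
    ProteinRecord,
    TranscriptModel,
)
from . import io as nio

# Canonical context fragments for the field's worked examples (KRAS exon-2
# hotspot region; histone H3.1/H3.3 N-terminal tails in mature-protein
# numbering, where K27M sits between the A21..A29 and M27..V35 registers).
KRAS_CONTEXT = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVD"
H3_1_CONTEXT = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHR"
H3_3_CONTEXT = "ARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGVKKPHR"

_COMP = str.maketrans("ACGTN", "TGCAN")

#: preferred codon per residue, chosen once (alphabetically first non-stop codon)
_AA_TO_CODON: dict[str, str] = {}
for codon in sorted(_CODON_TO_AA):
    aa = _CODON_TO_AA[codon]
    _AA_TO_CODON.setdefault(aa, codon)

_ALLELE_POOL = {
    "A": ["HLA-A*02:01", "HLA-A*11:01", "HLA-A*30:01", "HLA-A*68:02"],
    "B": ["HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:17", "HLA-B*44:02"],
    "C": ["HLA-C*03:04", "HLA-C*04:01", "HLA-C*07:01", "HLA-C*12:03"],
}

#: matches needed for the matrix scorer to clear 500 nM: the smallest m with
#: 50000**(1 - m/9) <= 500, i.e. m/9 >= 1 - ln(500)/ln(50000)
PLANT_MATCH_THRESHOLD = 4

DEFAULT_SEED = 20170831


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def reverse_translate(peptide: str) -> str:
    """A deterministic CDS (without stop) encoding the peptide."""
    return "".join(_AA_TO_CODON[aa] for aa in peptide)


@dataclass
class GeneFixture:
    """One synthetic gene: protein, transcript model, CDS and chromosome."""

    protein: ProteinRecord
    transcript: TranscriptModel
    cds: str  # transcript-strand coding sequence including the stop codon
    chrom_seq: str


@dataclass
class FixtureBundle:
    """All inputs for an end-to-end run plus the planted expected outputs."""

    seed: int
    genes: dict[str, GeneFixture]
    variants: list[MissenseVariant]
    fusions: list[FusionEvent]
    genotypes: list[HlaGenotype]
    matrices: dict[str, ScoringMatrix]
    sam_lines: list[str]
    contigs: dict[str, str]
    sample_meta: list[dict]
    truth: dict

    @property
    def proteins(self) -> list[ProteinRecord]:
        return [g.protein for g in self.genes.values()]

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [g.transcript for g in self.genes.values()]


# ---------------------------------------------------------------------------
# reference


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def _split_lengths(rng: np.random.Generator, total: int, n_parts: int) -> list[int]:
    """Split ``total`` (multiple of 3) into ``n_parts`` codon-aligned chunks."""
    codons = total // 3
    cuts = sorted(rng.choice(np.arange(1, codons), size=n_parts - 1, replace=False)) if n_parts > 1 else []
    bounds = [0, *cuts, codons]
    return [3 * (bounds[i + 1] - bounds[i]) for i in range(n_parts)]


def make_gene(
    rng: np.random.Generator,
    gene: str,
    peptide: str | None = None,
    aa_length: int = 60,
    n_exons: int = 1,
    strand: str = "+",
    pad: int = 100,
    intron: int = 50,
) -> GeneFixture:
    """Build one synthetic gene with its chromosome and transcript model."""
    if peptide is None:
        peptide = _random_peptide(rng, aa_length)
    if len(peptide) * 3 < 27:
        raise ValidationError("CDS must encode at least 9 residues (27 nt)")
    cds = reverse_translate(peptide) + "TAA"
    total = len(cds)

    lengths = _split_lengths(rng, total, n_exons)  # transcript-order exon lengths
    genomic_lengths = lengths if strand == "+" else list(reversed(lengths))
    exons = []
    cursor = pad
    for L in genomic_lengths:
        exons.append((cursor, cursor + L))
        cursor += L + intron
    chrom_len = cursor - intron + pad
    chrom = f"chr_{gene}"

    tx = TranscriptModel(
        tx_id=f"{gene}_T",
        gene=gene,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )
    positions = tx.coding_genomic_positions()
    assert len(positions) == total

    seq = list(rng.choice(list("ACGT"), size=chrom_len))
    for j, p in enumerate(positions):
        base = cds[j] if strand == "+" else cds[j].translate(_COMP)
        seq[p] = base
    protein = ProteinRecord(
        protein_id=f"{gene}_P",
        gene=gene,
        sequence=peptide,
        mrna_accession=f"{gene}_T",
        protein_gi=f"gi_{gene}",
    )
    return GeneFixture(protein=protein, transcript=tx, cds=cds, chrom_seq="".join(seq))


def make_reference(
    seed: int, n_genes: int = 6, aa_lengths: tuple[int, int] = (40, 80)
) -> dict[str, GeneFixture]:
    """Random genes (multi-exon, both strands) plus the fixed hotspot fragments."""
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneFixture] = {}
    for i in range(n_genes):
        name = f"GENE{i + 1:02d}"
        genes[name] = make_gene(
            rng,
            name,
            aa_length=int(rng.integers(aa_lengths[0], aa_lengths[1] + 1)),
            n_exons=int(rng.integers(1, 4)),
            strand="+" if i % 2 == 0 else "-",
        )
    genes["KRAS"] = make_gene(rng, "KRAS", peptide=KRAS_CONTEXT, n_exons=2)
    genes["HIST1H3B"] = make_gene(rng, "HIST1H3B", peptide=H3_1_CONTEXT)
    genes["H3F3A"] = make_gene(rng, "H3F3A", peptide=H3_3_CONTEXT, strand="-")
    return genes


# ---------------------------------------------------------------------------
# reads


def _blocks_from_positions(positions: list[int]) -> list[tuple[int, int]]:
    """Collapse a sorted position list into half-open runs."""
    runs = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        runs.append((start, prev + 1))
        start = prev = p
    runs.append((start, prev + 1))
    return runs


def _sam_read(
    read_id: str,
    chrom: str,
    positions: list[int],
    chrom_seq: str,
    subs: dict[int, str],
    sample: str = "",
) -> str:
    """One SAM alignment line covering exactly ``positions`` (M blocks, N gaps)."""
    positions = sorted(positions)
    runs = _blocks_from_positions(positions)
    cigar = []
    for i, (s, e) in enumerate(runs):
        if i:
            cigar.append(f"{s - runs[i - 1][1]}N")
        cigar.append(f"{e - s}M")
    seq = "".join(
        subs.get(p, chrom_seq[p]) for s, e in runs for p in range(s, e)
    )
    qual = "I" * len(seq)
    fields = [
        read_id, "0", chrom, str(runs[0][0] + 1), "60", "".join(cigar), "*", "0", "0", seq, qual,
    ]
    if sample:
        fields.append(f"RG:Z:{sample}")
    return "\t".join(fields)


# ---------------------------------------------------------------------------
# missense cases


@dataclass
class MissenseCase:
    """A planted missense variant with its reads and brute-forced window truth."""

    variant: MissenseVariant
    sam_lines: list[str]
    windows: list[tuple[int, str, str]]  # (0-based context offset, mutant, wild-type)
    context_start: int  # 1-based protein position of the context start
    expression: str  # "expressed" | "silent" | "none"


def _brute_force_windows(
    mutant: str, wildtype: str, aa_pos: int, k: int = 9
) -> tuple[list[tuple[int, str, str]], int]:
    """Enumerate every k-mer containing the mutated position by direct scan."""
    ctx_start0 = max(0, aa_pos - 1 - (k - 1))
    out = []
    for s0 in range(0, len(mutant) - k + 1):
        if s0 <= aa_pos - 1 <= s0 + k - 1:
            out.append((s0 - ctx_start0, mutant[s0 : s0 + k], wildtype[s0 : s0 + k]))
    return out, ctx_start0 + 1


def make_missense_case(
    rng: np.random.Generator,
    sample: str,
    gene_fx: GeneFixture,
    kind: str = "interior",
    expression: str = "expressed",
    k: int = 9,
) -> MissenseCase:
    """Plant one missense variant; reads realise the requested expression state.

    ``expressed`` places mutant reads spanning the full codon context of every
    window (so each window's 27 bases are covered); ``silent`` places mutant
    reads covering the variant base but never a full window; ``none`` places
    no reads (RNA unavailable).
    """
    protein, tx, cds = gene_fx.protein, gene_fx.transcript, gene_fx.cds
    La = len(protein.sequence)
    if kind == "interior":
        if La < 2 * k - 1:
            raise ValidationError(f"{protein.gene}: too short for an interior mutation")
        aa_pos = int(rng.integers(k, La - k + 2))  # k .. La-k+1 inclusive
    elif kind == "edge":
        aa_pos = 1 if rng.integers(2) == 0 else La
    else:
        raise ValidationError(f"unknown placement kind {kind!r}")

    codon = cds[3 * (aa_pos - 1) : 3 * aa_pos]
    aa_ref = protein.sequence[aa_pos - 1]
    choice = None
    for off in range(3):
        for base in "ACGT":
            if base == codon[off]:
                continue
            alt = codon[:off] + base + codon[off + 1 :]
            if alt in _STOPS:
                continue
            aa_alt = _CODON_TO_AA[alt]
            if aa_alt != aa_ref:
                choice = (off, base, aa_alt)
                break
        if choice:
            break
    assert choice is not None, "every sense codon admits a missense substitution"
    off, tx_base, aa_mut = choice

    positions = tx.coding_genomic_positions()
    g = positions[3 * (aa_pos - 1) + off]
    mut_plus = tx_base if tx.strand == "+" else tx_base.translate(_COMP)
    ref_plus = gene_fx.chrom_seq[g]

    total_t = int(rng.integers(30, 61))
    mut_t = int(rng.integers(8, max(9, total_t // 2)))
    variant = MissenseVariant(
        sample=sample,
        chrom=tx.chrom,
        pos=g + 1,
        ref_allele=ref_plus,
        mut_allele=mut_plus,
        gene=protein.gene,
        mrna_accession=tx.tx_id,
        aa_ref=aa_ref,
        aa_pos=aa_pos,
        aa_mut=aa_mut,
        mutant_reads_tumor=mut_t,
        total_reads_tumor=total_t,
        mutant_reads_normal=0,
        total_reads_normal=int(rng.integers(30, 61)),
    )

    mutant_seq = protein.sequence[: aa_pos - 1] + aa_mut + protein.sequence[aa_pos:]
    windows, context_start = _brute_force_windows(mutant_seq, protein.sequence, aa_pos, k)

    sam_lines = []
    if expression == "expressed":
        c_lo, c_hi = max(1, aa_pos - (k - 1)), min(La, aa_pos + (k - 1))
        span = positions[3 * (c_lo - 1) : 3 * c_hi]
        for i in range(2):
            sam_lines.append(
                _sam_read(
                    f"{sample}_{protein.gene}_mut{i}", tx.chrom, span, gene_fx.chrom_seq,
                    {g: mut_plus}, sample=sample,
                )
            )
        sam_lines.append(
            _sam_read(
                f"{sample}_{protein.gene}_wt0", tx.chrom, span, gene_fx.chrom_seq, {},
                sample=sample,
            )
        )
    elif expression == "silent":
        # mutant reads covering the site but fewer than 27 contiguous CDS bases
        exon = next((s, e) for s, e in tx.exons if s <= g < e)
        lo, hi = max(exon[0], g - 4), min(exon[1], g + 5)
        short = list(range(lo, hi))
        for i in range(3):
            sam_lines.append(
                _sam_read(
                    f"{sample}_{protein.gene}_short{i}", tx.chrom, short, gene_fx.chrom_seq,
                    {g: mut_plus}, sample=sample,
                )
            )
    elif expression != "none":
        raise ValidationError(f"unknown expression kind {expression!r}")

    return MissenseCase(
        variant=variant,
        sam_lines=sam_lines,
        windows=windows,
        context_start=context_start,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# fusion cases


@dataclass
class FusionCase:
    """A planted fusion with its junction contig, reads and window truth."""

    event: FusionEvent
    contig_name: str
    contig_seq: str
    sam_lines: list[str]
    windows: list[tuple[int, str]]  # (0-based peptide offset, nonamer)
    expression: str


def _brute_force_junction_windows(peptide: str, n5: int, k: int = 9) -> list[tuple[int, str]]:
    """Set-algebra enumeration: k-mers neither wholly 5' nor wholly 3'."""
    out = []
    for s0 in range(0, len(peptide) - k + 1):
        touches5 = touches3 = False
        for r in range(s0, s0 + k):  # 0-based residue, codon nt [3r, 3r+3)
            if 3 * r < n5:
                touches5 = True
            if 3 * r + 3 > n5:
                touches3 = True
        if touches5 and touches3:
            out.append((s0, peptide[s0 : s0 + k]))
    return out


def make_fusion_case(
    rng: np.random.Generator,
    sample: str,
    fx5: GeneFixture,
    fx3: GeneFixture,
    in_frame: bool = True,
    expression: str = "expressed",
    k: int = 9,
) -> FusionCase:
    """Plant one fusion event with junction contig and junction-spanning reads."""
    cds5 = fx5.cds[:-3]  # drop the 5' partner's stop codon
    cds3 = fx3.cds
    m = int(rng.integers(k + 1, len(cds5) // 3 - 1))
    n5 = 3 * m
    n3off = 3 * int(rng.integers(0, 3))
    if not in_frame:
        n5 += 1  # +1 frameshift

    pos5 = fx5.transcript.coding_genomic_positions()
    pos3 = fx3.transcript.coding_genomic_positions()
    event = FusionEvent(
        sample=sample,
        gene5=fx5.protein.gene,
        tx5=fx5.transcript.tx_id,
        bp5=pos5[n5 - 1],
        gene3=fx3.protein.gene,
        tx3=fx3.transcript.tx_id,
        bp3=pos3[n3off],
        n5=n5,
        n3off=n3off,
        junction_read_count=int(rng.integers(2, 12)),
    )

    contig = cds5[:n5] + cds3[n3off:]
    name = junction_contig_name(event)
    windows: list[tuple[int, str]] = []
    if in_frame:
        peptide = translate_cds(contig)
        windows = _brute_force_junction_windows(peptide, n5, k)

    sam_lines = []
    if expression == "expressed" and windows:
        lo = 3 * windows[0][0]
        hi = 3 * windows[-1][0] + 3 * k
        span = list(range(lo, hi))
        for i in range(2):
            sam_lines.append(_sam_read(f"{sample}_jct{i}", name, span, contig, {}, sample=sample))
    elif expression == "silent":
        five_side = list(range(0, max(9, n5 - 3)))
        sam_lines.append(_sam_read(f"{sample}_jct5p", name, five_side, contig, {}, sample=sample))

    return FusionCase(
        event=event,
        contig_name=name,
        contig_seq=contig,
        sam_lines=sam_lines,
        windows=windows,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# binding world


def make_binding_world(
    alleles: list[str],
    planted: dict[str, set[str]],
    universe: list[str] | None = None,
) -> dict[str, ScoringMatrix]:
    """Scoring matrices guaranteeing planted pairs pass 500 nM and others fail.

    Each allele's matrix carries weight 1 at the planted peptides' residues
    and 0 elsewhere, so a 9-mer passes exactly when it matches the planted
    residue profile at >= 4 of 9 positions.  When a candidate ``universe`` is
    supplied, every non-planted (peptide, allele) pair is checked against the
    profile and a collision raises :class:`InfeasiblePlantError`.
    """
    res_index = {aa: i for i, aa in enumerate(RESIDUES)}
    matrices = {}
    for allele in sorted(set(alleles)):
        weights = np.zeros((9, len(RESIDUES)))
        for pep in sorted(planted.get(allele, set())):
            if len(pep) != 9:
                raise InfeasiblePlantError(f"planted peptide {pep!r} is not a 9-mer")
            for i, aa in enumerate(pep):
                weights[i, res_index[aa]] = 1.0
        matrices[allele] = ScoringMatrix(allele=allele, weights=tuple(map(tuple, weights)))
    if universe is not None:
        for allele in matrices:
            profile = _profile(matrices[allele])
            for pep in universe:
                if pep in planted.get(allele, set()):
                    continue
                if _profile_matches(pep, profile) >= PLANT_MATCH_THRESHOLD:
                    raise InfeasiblePlantError(
                        f"non-planted peptide {pep} would pass for {allele}"
                    )
    return matrices


def _profile(matrix: ScoringMatrix) -> list[set[str]]:
    return [
        {RESIDUES[j] for j, w in enumerate(row) if w >= 1.0} for row in matrix.weights
    ]


def _profile_matches(peptide: str, profile: list[set[str]]) -> int:
    return sum(1 for i, aa in enumerate(peptide) if aa in profile[i])


def truth_binds(peptide: str, allele: str, matrices: dict[str, ScoringMatrix]) -> bool:
    """Independent pass/fail rule: >= 4 of 9 residues on the allele's profile."""
    m = matrices.get(allele)
    if m is None:
        return False
    return _profile_matches(peptide, _profile(m)) >= PLANT_MATCH_THRESHOLD


# ---------------------------------------------------------------------------
# genotypes and concordance cohorts


def make_genotype(rng: np.random.Generator, sample: str) -> HlaGenotype:
    alleles = []
    for locus in ("A", "B", "C"):
        pool = _ALLELE_POOL[locus]
        alleles.extend(rng.choice(pool, size=2, replace=True))
    return HlaGenotype(sample=sample, alleles=tuple(alleles))


def make_concordance_cohort(
    seed: int, n_samples: int = 51, n_allele_errors: int = 18
) -> tuple[list[HlaGenotype], list[HlaGenotype], int]:
    """Truth/called genotype pairs with exactly ``n_allele_errors`` wrong alleles.

    Each error converts one locus into a heterozygous call with one matching
    allele (one correct allele lost), so the expected correct-allele count is
    ``6 * n_samples - n_allele_errors``.
    """
    if n_allele_errors > 3 * n_samples:
        raise ValidationError("at most one error per locus is supported")
    rng = np.random.default_rng(seed)
    truth, called = [], []
    slots = [(i, locus) for i in range(n_samples) for locus in ("A", "B", "C")]
    err_idx = rng.choice(len(slots), size=n_allele_errors, replace=False)
    err_slots = {slots[i] for i in err_idx}
    for i in range(n_samples):
        sample = f"SJVAL{i + 1:03d}"
        g = make_genotype(rng, sample)
        called_alleles = list(g.alleles)
        for locus_i, locus in enumerate(("A", "B", "C")):
            if (i, locus) not in err_slots:
                continue
            pair_lo = 2 * locus_i
            current = called_alleles[pair_lo : pair_lo + 2]
            wrong = next(
                a for a in _ALLELE_POOL[locus] if a not in current
            )
            called_alleles[pair_lo + 1] = wrong
        truth.append(g)
        called.append(HlaGenotype(sample=sample, alleles=tuple(called_alleles)))
    return truth, called, 6 * n_samples - n_allele_errors


# ---------------------------------------------------------------------------
# full bundle


_SUBTYPES = ("BALL", "HGG", "OS")


def make_bundle(
    seed: int = DEFAULT_SEED,
    n_samples: int = 8,
    n_random_genes: int = 6,
    variants_per_sample: tuple[int, int] = (2, 4),
    plant_rate: float = 0.7,
) -> FixtureBundle:
    """A full synthetic cohort with planted truth for end-to-end recovery."""
    rng = np.random.default_rng(seed)
    genes = make_reference(int(rng.integers(1, 2**31)), n_genes=n_random_genes)
    gene_names = sorted(genes)

    sam_lines: list[str] = []
    contigs: dict[str, str] = {}
    variants: list[MissenseVariant] = []
    fusions: list[FusionEvent] = []
    genotypes: list[HlaGenotype] = []
    sample_meta: list[dict] = []
    cases: list[MissenseCase] = []
    fusion_cases: list[FusionCase] = []
    planted: dict[str, set[str]] = {}
    planned: list[dict] = []  # per-sample window inventory for truth assembly

    for i in range(n_samples):
        subtype = _SUBTYPES[i % len(_SUBTYPES)]
        sample = f"SJ{subtype}{i + 1:03d}"
        rna = i % 4 != 3
        relapse = i == n_samples - 1
        genotype = make_genotype(rng, sample)
        genotypes.append(genotype)
        sample_meta.append(
            {"sample": sample, "subtype": subtype, "rna_available": rna, "relapse": relapse}
        )

        n_var = int(rng.integers(variants_per_sample[0], variants_per_sample[1] + 1))
        chosen_genes = rng.choice(gene_names, size=n_var, replace=False)
        sample_windows: list[tuple[str, str, list[str], str]] = []
        for j, gname in enumerate(chosen_genes):
            kind = "edge" if (i + j) % 5 == 4 else "interior"
            if not rna:
                expression = "none"
            else:
                expression = "expressed" if rng.random() < 0.6 else "silent"
            case = make_missense_case(rng, sample, genes[gname], kind, expression)
            cases.append(case)
            variants.append(case.variant)
            sam_lines.extend(case.sam_lines)
            sample_windows.append(
                (
                    case.variant.lesion_key,
                    "missense",
                    [w[1] for w in case.windows],
                    expression,
                )
            )

        if i % 2 == 0:
            in_frame = i % 6 != 4
            g5, g3 = rng.choice(gene_names, size=2, replace=False)
            fexpr = "expressed" if rna else "none"
            fcase = make_fusion_case(rng, sample, genes[g5], genes[g3], in_frame, fexpr)
            fusion_cases.append(fcase)
            fusions.append(fcase.event)
            sam_lines.extend(fcase.sam_lines)
            contigs[fcase.contig_name] = fcase.contig_seq
            if fcase.windows:
                sample_windows.append(
                    (
                        fcase.event.lesion_key,
                        "fusion",
                        [w[1] for w in fcase.windows],
                        fexpr,
                    )
                )

        # plant one window of most lesions as a binder for one sample allele
        for lesion, source, peptides, expression in sample_windows:
            if rng.random() < plant_rate and peptides:
                pep = peptides[int(rng.integers(len(peptides)))]
                allele = genotype.distinct_alleles()[
                    int(rng.integers(len(genotype.distinct_alleles())))
                ]
                if "X" not in pep:
                    planted.setdefault(allele, set()).add(pep)
        planned.append(
            {"sample": sample, "windows": sample_windows, "genotype": genotype, "rna": rna}
        )

    all_alleles = sorted({a for g in genotypes for a in g.alleles})
    matrices = make_binding_world(all_alleles, planted)

    # truth: evaluate every window against the sample's alleles with the
    # independent >= 4-match rule, carrying the case's expression flag
    truth_candidates = []
    truth_samples = {}
    for entry in planned:
        sample = entry["sample"]
        genotype: HlaGenotype = entry["genotype"]
        rna = entry["rna"]
        pairs = set()
        expressed_pairs = set()
        lesions_with_candidates = set()
        for lesion, source, peptides, expression in entry["windows"]:
            for pep in peptides:
                if "X" in pep:
                    continue
                for allele in genotype.distinct_alleles():
                    if truth_binds(pep, allele, matrices):
                        flag = {"expressed": "yes", "silent": "no", "none": "unknown"}[
                            expression
                        ]
                        truth_candidates.append(
                            {
                                "sample": sample,
                                "peptide": pep,
                                "allele": allele,
                                "source": source,
                                "source_key": lesion,
                                "expressed": flag,
                            }
                        )
                        pairs.add((pep, allele))
                        if flag == "yes":
                            expressed_pairs.add((pep, allele))
                        if source == "missense":
                            lesions_with_candidates.add(lesion)
        n_missense = sum(1 for v in variants if v.sample == sample)
        truth_samples[sample] = {
            "n_missense": n_missense,
            "n_neoepitope_mutations": len(
                {
                    v.lesion_key
                    for v in variants
                    if v.sample == sample and v.lesion_key in lesions_with_candidates
                }
            ),
            "n_candidates": len(pairs),
            "n_expressed_candidates": len(expressed_pairs) if rna else None,
        }

    truth = {
        "seed": seed,
        "candidates": sorted(
            truth_candidates,
            key=lambda c: (c["sample"], c["source_key"], c["peptide"], c["allele"]),
        ),
        "samples": truth_samples,
        "windows": {
            c.variant.key: sorted(w[1] for w in c.windows) for c in cases
        },
        "junction_windows": {
            fc.event.key: [w[1] for w in fc.windows] for fc in fusion_cases
        },
    }
    return FixtureBundle(
        seed=seed,
        genes=genes,
        variants=variants,
        fusions=fusions,
        genotypes=genotypes,
        matrices=matrices,
        sam_lines=sam_lines,
        contigs=contigs,
        sample_meta=sample_meta,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialisation


def write_bundle(bundle: FixtureBundle, outdir) -> dict[str, str]:
    """Write the bundle as the pipeline's on-disk input formats plus truth.json."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.fasta",
        "cds": out / "cds.fasta",
        "genome": out / "genome.fasta",
        "transcripts": out / "transcripts.tsv",
        "variants": out / "variants.tsv",
        "fusions": out / "fusions.tsv",
        "hla": out / "hla.tsv",
        "reads": out / "reads.sam",
        "contigs": out / "contigs.fasta",
        "matrices": out / "matrices.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    nio.write_protein_fasta(bundle.proteins, paths["proteins"])
    nio.write_sequence_fasta(
        {g.transcript.tx_id: g.cds for g in bundle.genes.values()}, paths["cds"]
    )
    nio.write_sequence_fasta(
        {g.transcript.chrom: g.chrom_seq for g in bundle.genes.values()}, paths["genome"]
    )
    nio.write_transcript_models(bundle.transcripts, paths["transcripts"])
    nio.write_variant_matrix(bundle.variants, paths["variants"])
    nio.write_fusion_table(bundle.fusions, paths["fusions"])
    nio.write_hla_calls(bundle.genotypes, paths["hla"])
    nio.write_sequence_fasta(bundle.contigs, paths["contigs"])
    write_matrices(bundle.matrices, paths["matrices"])

    with open(paths["reads"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for g in sorted(bundle.genes.values(), key=lambda g: g.transcript.chrom):
            fh.write(f"@SQ\tSN:{g.transcript.chrom}\tLN:{len(g.chrom_seq)}\n")
        for name in sorted(bundle.contigs):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(bundle.contigs[name])}\n")
        for m in bundle.sample_meta:
            fh.write(f"@RG\tID:{m['sample']}\tSM:{m['sample']}\n")
        for line in bundle.sam_lines:
            fh.write(line + "\n")

    import pandas as pd

    with open(paths["samples"], "w") as fh:
        fh.write("#neoscan\tsamples\tv1\n")
        pd.DataFrame(bundle.sample_meta).to_csv(fh, sep="\t", index=False)

    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
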