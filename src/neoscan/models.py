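"""Domain types shared across the neoepitope pipeline.

Coordinate conventions
----------------------
Genomic coordinates are 0-based half-open everywhere inside the package;
file readers convert from the 1-based inclusive convention of the tabular
inputs exactly once (``MissenseVariant.pos`` keeps the 1-based value as read,
``MissenseVariant.pos0`` exposes the internal 0-based index).  Protein
positions are 1-based throughout, matching the p.G13D style of annotation.

HLA class I alleles are handled at two-field ("protein") resolution and
normalised to the ``HLA-A*02:01`` form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

#: The 20 standard amino acids, in the fixed column order used by scoring matrices.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(RESIDUES)
_AA_OR_X = _AA_SET | {"X"}

_ALLELE_RE = re.compile(r"^(?:HLA-)?([ABC])\s*\*?\s*(\d{1,3}):(\d{1,3})((?::\d+)*[A-Z]?)$")


def normalize_allele(name: str) -> str:
    """Normalise an HLA class I allele name to two-field ``HLA-A*02:01`` form.

    Accepts bare (``A*02:01``), starred or unstarred (``HLA-A02:01``) spellings;
    higher-resolution fields (``HLA-A*02:01:01``) are truncated to two fields.

    Raises
    ------
    ValidationError
        If the token cannot be interpreted as a class I allele.
    """
    m = _ALLELE_RE.match(name.strip())
    if not m:
        raise ValidationError(f"unparseable HLA allele name: {name!r}")
    locus, f1, f2 = m.group(1), int(m.group(2)), int(m.group(3))
    return f"HLA-{locus}*{f1:02d}:{f2:02d}"


def allele_locus(allele: str) -> str:
    """Return the locus letter (A, B or C) of a normalised allele name."""
    m = _ALLELE_RE.match(allele)
    if not m:
        raise ValidationError(f"not an HLA class I allele: {allele!r}")
    return m.group(1)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence tied to a transcript/protein accession."""

    protein_id: str
    gene: str
    sequence: str
    mrna_accession: str = ""
    protein_gi: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"{self.protein_id}: empty protein sequence")
        bad = set(self.sequence) - _AA_OR_X
        if bad:
            raise ValidationError(
                f"{self.protein_id}: non-standard residues {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of a coding transcript, used to map codons to the genome.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order regardless of strand; ``cds_start``/``cds_end`` delimit the coding
    span in genomic coordinates (half-open).
    """

    tx_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"{self.tx_id}: strand must be + or -")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.tx_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValidationError(f"{self.tx_id}: exons overlap or are unsorted")
            prev_end = e
        if not self.cds_start < self.cds_end:
            raise ValidationError(f"{self.tx_id}: cds_start must be < cds_end")

    @property
    def cds_length(self) -> int:
        return len(self.coding_genomic_positions())

    @property
    def complete(self) -> bool:
        """True when the CDS length is a whole number of codons."""
        return self.cds_length % 3 == 0

    def coding_genomic_positions(self) -> list[int]:
        """Genomic position of every coding base, in transcript (5'->3') order.

        Positions ascend genomically on the plus strand and descend on the
        minus strand.
        """
        pos: list[int] = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                pos.extend(range(lo, hi))
        if self.strand == "-":
            pos.reverse()
        return pos


@dataclass(frozen=True)
class MissenseVariant:
    """One somatic missense SNV with its read-count evidence.

    ``pos`` is the 1-based genomic coordinate as read from the variant table;
    ``pos0`` is the internal 0-based index.
    """

    sample: str
    chrom: str
    pos: int
    ref_allele: str
    mut_allele: str
    gene: str
    mrna_accession: str
    aa_ref: str
    aa_pos: int
    aa_mut: str
    mutation_class: str = "missense"
    mutant_reads_tumor: int = 0
    total_reads_tumor: int = 0
    mutant_reads_normal: int = 0
    total_reads_normal: int = 0

    def __post_init__(self):
        if self.aa_ref == self.aa_mut:
            raise ValidationError(
                f"{self.sample} {self.gene}: reference and mutant residue are both "
                f"{self.aa_ref!r} at position {self.aa_pos}"
            )
        if self.mutant_reads_tumor > self.total_reads_tumor:
            raise ValidationError(f"{self.sample} {self.gene}: tumor mutant reads exceed total")
        if self.mutant_reads_normal > self.total_reads_normal:
            raise ValidationError(f"{self.sample} {self.gene}: normal mutant reads exceed total")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def protein_change(self) -> str:
        return f"p.{self.aa_ref}{self.aa_pos}{self.aa_mut}"

    @property
    def lesion_key(self) -> str:
        """Cohort-level identifier of the lesion (gene + protein change)."""
        return f"{self.gene}:{self.protein_change}"

    @property
    def key(self) -> str:
        return f"{self.sample}|{self.lesion_key}"


@dataclass(frozen=True)
class FusionEvent:
    """A transcript-level fusion breakpoint pair with retained-CDS arithmetic.

    ``n5`` counts coding nucleotides of the 5' partner retained up to the
    breakpoint; ``n3off`` is the coding-nucleotide offset of the 3' breakpoint
    from the 3' partner's CDS start.
    """

    sample: str
    gene5: str
    tx5: str
    bp5: int
    gene3: str
    tx3: str
    bp3: int
    n5: int
    n3off: int
    junction_read_count: int = 0

    def __post_init__(self):
        if self.n5 < 0 or self.n3off < 0:
            raise ValidationError(f"{self.sample} {self.lesion_key}: negative coding offsets")
        if self.junction_read_count < 0:
            raise ValidationError(f"{self.sample} {self.lesion_key}: negative junction read count")

    @property
    def lesion_key(self) -> str:
        return f"{self.gene5}-{self.gene3}"

    @property
    def key(self) -> str:
        return f"{self.sample}|{self.lesion_key}:{self.bp5}-{self.bp3}"


_LOCI = ("A", "B", "C")


@dataclass(frozen=True)
class HlaGenotype:
    """Six two-field class I alleles (HLA-A x2, HLA-B x2, HLA-C x2) for one sample."""

    sample: str
    alleles: tuple[str, ...]

    def __post_init__(self):
        normalized = tuple(normalize_allele(a) for a in self.alleles)
        object.__setattr__(self, "alleles", normalized)
        by_locus = {l: [a for a in normalized if allele_locus(a) == l] for l in _LOCI}
        for locus, found in by_locus.items():
            if len(found) != 2:
                raise ValidationError(
                    f"{self.sample}: expected 2 HLA-{locus} alleles, found {len(found)}"
                )

    def locus(self, locus: str) -> tuple[str, str]:
        pair = tuple(a for a in self.alleles if allele_locus(a) == locus)
        return pair  # type: ignore[return-value]

    def distinct_alleles(self) -> list[str]:
        """The sample's distinct alleles in a stable (sorted) order."""
        return sorted(set(self.alleles))


@dataclass(frozen=True)
class PeptidePrecursor:
    """A tiling window peptide awaiting binding prediction.

    ``window_offset`` is the 0-based start of the window within its source
    peptide context (the mutation +/- 8 context for missense windows, the
    junction peptide for fusion windows).
    """

    sample: str
    peptide: str
    wt_peptide: str
    source: str  # "missense" | "fusion"
    source_key: str
    window_offset: int
    scorable: bool = True


EXPRESSED_STATES = ("yes", "no", "unknown")


@dataclass
class CandidateEpitope:
    """A peptide-allele pair passing the binding filter, with provenance."""

    sample: str
    peptide: str
    wt_peptide: str
    allele: str
    ic50_nM: float
    source: str
    source_key: str
    window_offset: int
    expressed: str = "unknown"

    def __post_init__(self):
        if self.ic50_nM <= 0:
            raise ValidationError(f"{self.key}: IC50 must be positive")
        if self.source == "missense":
            diffs = sum(a != b for a, b in zip(self.peptide, self.wt_peptide))
            if len(self.peptide) != len(self.wt_peptide) or diffs != 1:
                raise ValidationError(
                    f"{self.key}: missense mutant/wild-type nonamers must differ at exactly one position"
                )
        if self.expressed not in EXPRESSED_STATES:
            raise ValidationError(f"{self.key}: bad expression state {self.expressed!r}")

    @property
    def key(self) -> str:
        return f"{self.sample}|{self.source_key}|{self.window_offset}|{self.peptide}|{self.allele}"


@dataclass(frozen=True)
class AlignedRead:
    """A single aligned RNA-seq read reduced to its reference-matching blocks.

    ``blocks`` holds ``(ref_start, ref_end, query_offset)`` triples for every
    CIGAR run that consumes both reference and query (M, =, X); deletions and
    splice gaps break blocks.
    """

    read_id: str
    chrom: str
    start: int
    blocks: tuple[tuple[int, int, int], ...]
    query_sequence: str
    mapq: int = 60
    base_qualities: tuple[int, ...] | None = None
    sample: str = ""  # read-group sample; empty when the alignment carries no RG tag

    def __post_init__(self):
        prev_end = -1
        for rs, re_, _ in self.blocks:
            if rs >= re_:
                raise ValidationError(f"{self.read_id}: empty aligned block")
            if rs < prev_end:
                raise ValidationError(f"{self.read_id}: aligned blocks overlap or are unsorted")
            prev_end = re_

    def covers(self, pos: int) -> bool:
        """True when genomic position ``pos`` falls inside an aligned match block."""
        return any(rs <= pos < re_ for rs, re_, _ in self.blocks)

    def base_at(self, pos: int) -> str | None:
        """The aligned query base at genomic position ``pos``, or None if uncovered."""
        for rs, re_, qoff in self.blocks:
            if rs <= pos < re_:
                return self.query_sequence[qoff + (pos - rs)]
        return None

    def quality_at(self, pos: int) -> int | None:
        if self.base_qualities is None:
            return None
        for rs, re_, qoff in self.blocks:
            if rs <= pos < re_:
                return self.base_qualities[qoff + (pos - rs)]
        return None


@dataclass(frozen=True)
class WindowSet:
    """The tiling mutant/wild-type nonamer pairs around one missense mutation."""

    variant_key: str
    mutant_context: str
    context_start: int  # 1-based protein position of the first context residue
    windows: tuple[tuple[int, str, str], ...]  # (offset within context, mutant, wild-type)


@dataclass(frozen=True)
class JunctionPeptide:
    """The translated fusion-junction peptide and its breakpoint bookkeeping."""

    fusion_key: str
    junction_cds: str
    peptide: str
    junction_residue_span: tuple[int, int]  # 1-based inclusive peptide positions
    in_frame: bool
    n5: int = 0  # coding nucleotides retained from the 5' partner


@dataclass(frozen=True)
class ExpressionCall:
    """RNA-seq support for one candidate's 27-base window."""

    candidate_key: str
    mutant_read_count: int
    spanning_mutant_read_count: int
    expressed: bool

    def __post_init__(self):
        if self.spanning_mutant_read_count > self.mutant_read_count:
            raise ValidationError(
                f"{self.candidate_key}: spanning reads exceed mutant-supporting reads"
            )
        # Under the default strict rule expressed <=> spanning >= 1; the relaxed
        # any-read-spans mode may set expressed without a mutant spanning read,
        # so only the forward implication is enforced here.
        if self.spanning_mutant_read_count >= 1 and not self.expressed:
            raise ValidationError(
                f"{self.candidate_key}: spanning mutant read present but expressed is False"
            )


@dataclass(frozen=True)
class LocusConcordance:
    """Per-sample, per-locus agreement between truth and called HLA genotypes."""

    sample: str
    locus: str
    correct_alleles: int
    truth_pair: tuple[str, str]
    called_pair: tuple[str, str]

    def __post_init__(self):
        if not 0 <= self.correct_alleles <= 2:
            raise ValidationError(f"{self.sample} HLA-{self.locus}: correct_alleles outside 0..2")


@dataclass
class SampleSummary:
    """Per-sample landscape counts (predicted and expressed neoepitopes)."""

    sample: str
    subtype: str
    n_missense: int
    n_neoepitope_mutations: int
    n_candidates: int
    n_expressed_candidates: int | None
    rna_available: bool
    relapse: bool = False

    def __post_init__(self):
        if self.n_neoepitope_mutations > self.n_missense:
            raise ValidationError(
                f"{self.sample}: more neoepitope-bearing mutations than missense mutations"
            )
        if (
            self.n_expressed_candidates is not None
            and self.n_expressed_candidates > self.n_candidates
        ):
            raise ValidationError(f"{self.sample}: expressed candidates exceed candidates")


@dataclass(frozen=True)
class RecurrenceSummary:
    """How often a recurrent lesion yields a predicted neoepitope across carriers."""

    lesion: str
    n_samples_total: int
    n_samples_with_epitope: int

    def __post_init__(self):
        if self.n_samples_with_epitope > self.n_samples_total:
            raise ValidationError(f"{self.lesion}: epitope-positive carriers exceed carriers")
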