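"""RNA-seq expression evidence for candidate neoepitopes.

A candidate nonamer is called expressed when at least one RNA-seq read both
carries the mutant allele and spans, within its aligned match blocks, all 27
genomic bases encoding the nonamer.  Splice gaps between blocks are allowed
(they are transcript-consistent); a deletion overlapping any window base
breaks spanning.  For fusion candidates the reads are alignments to the
junction contig and the mutant-allele test is vacuous: the junction itself is
the somatic lesion.
"""

from __future__ import annotations

import logging

from .errors import ValidationError
from .models import (
    AlignedRead,
    CandidateEpitope,
    ExpressionCall,
    MissenseVariant,
    TranscriptModel,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_BASE_QUALITY = 20
DEFAULT_MIN_MAPQ = 1


def window_genomic_positions(
    tx: TranscriptModel, aa_window_start: int, k: int = 9
) -> list[int]:
    """Genomic coordinates of the 3k bases encoding a k-mer window.

    Positions are returned in transcript (5'->3') order, honouring strand and
    exon structure, so a window straddling an intron yields two genomic runs
    and a minus-strand window descends genomically.
    """
    cds = tx.coding_genomic_positions()
    lo = (aa_window_start - 1) * 3
    hi = lo + 3 * k
    if aa_window_start < 1 or hi > len(cds):
        raise ValidationError(
            f"{tx.tx_id}: window at protein position {aa_window_start} (k={k}) "
            f"extends past the CDS ({len(cds)} nt)"
        )
    return cds[lo:hi]


def read_supports_mutant(
    read: AlignedRead,
    variant: MissenseVariant,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> bool:
    """True when the read's aligned base at the variant position is the mutant allele.

    The comparison is on the reference/plus strand as aligned.  A read whose
    deletion or splice gap covers the site, or that does not reach it, returns
    False; so does a base below the quality cutoff when qualities are present.
    """
    if read.chrom != variant.chrom:
        return False
    base = read.base_at(variant.pos0)
    if base is None:
        return False
    q = read.quality_at(variant.pos0)
    if q is not None and q < min_base_quality:
        return False
    return base.upper() == variant.mut_allele.upper()


def read_spans_window(read: AlignedRead, positions: list[int]) -> bool:
    """True when every window position lies inside one of the read's match blocks."""
    return all(read.covers(p) for p in positions)


def call_expression(
    candidate: CandidateEpitope,
    variant: MissenseVariant,
    tx: TranscriptModel,
    reads: list[AlignedRead],
    k: int | None = None,
    strict_mutant_spanning: bool = True,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> ExpressionCall:
    """Apply the full-span expression rule to one missense candidate.

    The candidate's window offset is relative to the mutation +/- (k-1)
    context, so the window's first protein position is recovered from the
    variant.  With ``strict_mutant_spanning`` (default) the spanning read must
    itself carry the mutant allele; relaxing it accepts any read spanning the
    window, for sensitivity analysis.
    """
    if candidate.source != "missense":
        raise ValidationError(f"{candidate.key}: call_expression handles missense candidates")
    if candidate.sample != variant.sample or candidate.source_key != variant.lesion_key:
        raise ValidationError(f"{candidate.key}: candidate does not derive from {variant.key}")
    k = k if k is not None else len(candidate.peptide)
    context_start = max(1, variant.aa_pos - (k - 1))
    aa_window_start = context_start + candidate.window_offset
    positions = window_genomic_positions(tx, aa_window_start, k)

    mutant_reads = [
        r for r in reads if read_supports_mutant(r, variant, min_base_quality=min_base_quality)
    ]
    spanning_mutant = [r for r in mutant_reads if read_spans_window(r, positions)]
    if strict_mutant_spanning:
        expressed = len(spanning_mutant) >= 1
    else:
        expressed = any(
            r.chrom == variant.chrom and read_spans_window(r, positions) for r in reads
        )
    return ExpressionCall(
        candidate_key=candidate.key,
        mutant_read_count=len(mutant_reads),
        spanning_mutant_read_count=len(spanning_mutant),
        expressed=expressed,
    )


def fusion_window_expression(
    candidate: CandidateEpitope,
    contig: str,
    reads: list[AlignedRead],
    k: int | None = None,
) -> ExpressionCall:
    """Apply the full-span rule to a fusion candidate on its junction contig.

    The junction contig carries the assembled junction CDS, so the 27 bases
    encoding the window at peptide offset ``w`` are contig positions
    ``3w .. 3w + 27``.  Any read spanning them evidences the fusion product.
    """
    if candidate.source != "fusion":
        raise ValidationError(f"{candidate.key}: fusion_window_expression handles fusion candidates")
    k = k if k is not None else len(candidate.peptide)
    positions = list(range(3 * candidate.window_offset, 3 * candidate.window_offset + 3 * k))
    on_contig = [r for r in reads if r.chrom == contig]
    spanning = [r for r in on_contig if read_spans_window(r, positions)]
    return ExpressionCall(
        candidate_key=candidate.key,
        mutant_read_count=len(spanning),
        spanning_mutant_read_count=len(spanning),
        expressed=len(spanning) >= 1,
    )
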