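"""Tiling nonamer windows around somatic missense mutations.

A missense substitution at protein position ``p`` can sit at any of the nine
registers of a 9-mer, so the mutant peptide context spans ``p - 8 .. p + 8``
(clipped at the protein termini) and yields up to nine tiling nonamers, each
paired with the wild-type nonamer at the same offset.
"""

from __future__ import annotations

import logging

from .errors import ValidationError
from .models import MissenseVariant, PeptidePrecursor, ProteinRecord, WindowSet, _AA_SET

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 9


def apply_missense(protein: ProteinRecord, aa_pos: int, aa_ref: str, aa_mut: str) -> str:
    """Return the protein sequence with the single substitution applied.

    The residue found at ``aa_pos`` (1-based) must equal ``aa_ref``; a mismatch
    usually signals transcript-version drift between the variant annotation and
    the supplied protein and is reported as such.
    """
    seq = protein.sequence
    if not 1 <= aa_pos <= len(seq):
        raise ValidationError(
            f"{protein.protein_id}: position {aa_pos} outside protein of length {len(seq)}"
        )
    found = seq[aa_pos - 1]
    if found != aa_ref:
        raise ValidationError(
            f"{protein.protein_id}: expected reference residue {aa_ref!r} at position "
            f"{aa_pos}, found {found!r} (transcript-version drift?)"
        )
    return seq[: aa_pos - 1] + aa_mut + seq[aa_pos:]


def tiling_windows(sequence: str, pos: int, k: int = DEFAULT_WINDOW) -> list[tuple[int, str]]:
    """Every length-``k`` substring of ``sequence`` containing 1-based position ``pos``.

    Returns ``(offset, kmer)`` pairs with 0-based offsets, in ascending start
    order.  For an interior position of a long sequence this is exactly ``k``
    windows; positions within ``k - 1`` residues of a terminus yield fewer, and
    sequences shorter than ``k`` yield none (with a logged warning).
    """
    if k < 1:
        raise ValidationError(f"window length must be >= 1, got {k}")
    L = len(sequence)
    if not 1 <= pos <= L:
        raise ValidationError(f"position {pos} outside sequence of length {L}")
    if L < k:
        log.warning("sequence of length %d is shorter than window %d; no windows", L, k)
        return []
    first = max(1, pos - k + 1)
    last = min(pos, L - k + 1)
    return [(s - 1, sequence[s - 1 : s - 1 + k]) for s in range(first, last + 1)]


def missense_candidates(
    protein: ProteinRecord, variant: MissenseVariant, k: int = DEFAULT_WINDOW
) -> WindowSet:
    """Pair mutant tiling windows with wild-type windows at the same offsets.

    The mutant context is the mutation +/- (k-1) residues clipped to the
    termini; offsets in the returned :class:`WindowSet` are relative to that
    context.
    """
    if variant.mrna_accession and protein.mrna_accession:
        if variant.mrna_accession != protein.mrna_accession:
            raise ValidationError(
                f"variant {variant.key} annotated on {variant.mrna_accession}, "
                f"protein record is {protein.mrna_accession}"
            )
    mutant_seq = apply_missense(protein, variant.aa_pos, variant.aa_ref, variant.aa_mut)
    wt_seq = protein.sequence

    ctx_start0 = max(0, variant.aa_pos - 1 - (k - 1))
    ctx_end0 = min(len(mutant_seq), variant.aa_pos - 1 + k)
    context = mutant_seq[ctx_start0:ctx_end0]

    windows = []
    for off0, mut_kmer in tiling_windows(mutant_seq, variant.aa_pos, k):
        wt_kmer = wt_seq[off0 : off0 + k]
        windows.append((off0 - ctx_start0, mut_kmer, wt_kmer))
    return WindowSet(
        variant_key=variant.key,
        mutant_context=context,
        context_start=ctx_start0 + 1,
        windows=tuple(windows),
    )


def window_precursors(ws: WindowSet, variant: MissenseVariant) -> list[PeptidePrecursor]:
    """Turn a :class:`WindowSet` into scoring precursors.

    Windows containing a residue outside the 20 standard amino acids (e.g. an
    'X' placeholder) are emitted but flagged non-scorable, since binding
    matrices only cover the standard alphabet.
    """
    out = []
    for off, mut, wt in ws.windows:
        out.append(
            PeptidePrecursor(
                sample=variant.sample,
                peptide=mut,
                wt_peptide=wt,
                source="missense",
                source_key=variant.lesion_key,
                window_offset=off,
                scorable=set(mut) <= _AA_SET,
            )
        )
    return out
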