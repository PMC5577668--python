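"""Fusion-junction coding sequence assembly, frame arithmetic and translation.

A gene fusion joins ``n5`` coding nucleotides of the 5' partner to the 3'
partner's CDS starting at coding offset ``n3off``.  The chimera keeps the 3'
partner's native codon register downstream of the junction exactly when
``(n5 - n3off) mod 3 == 0``; only such in-frame events are translated into
junction peptides, and only nonamers overlapping the breakpoint are emitted.
"""

from __future__ import annotations

import logging

from Bio.Data import CodonTable

from .errors import ValidationError
from .models import FusionEvent, JunctionPeptide, PeptidePrecursor, _AA_SET

log = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOPS = set(_STANDARD.stop_codons)


def is_in_frame(n5: int, n3off: int) -> bool:
    """True when the 3' partner's codons stay in register downstream of the join."""
    if n5 < 0 or n3off < 0:
        raise ValidationError("coding nucleotide counts must be non-negative")
    return (n5 - n3off) % 3 == 0


def build_junction_cds(cds5: str, n5: int, cds3: str, n3off: int) -> str:
    """Concatenate the retained 5' coding prefix with the 3' coding suffix."""
    if not 0 <= n5 <= len(cds5):
        raise ValidationError(f"n5={n5} outside 5' CDS of length {len(cds5)}")
    if not 0 <= n3off <= len(cds3):
        raise ValidationError(f"n3off={n3off} outside 3' CDS of length {len(cds3)}")
    return cds5[:n5] + cds3[n3off:]


def translate_cds(cds: str) -> str:
    """Standard-code translation, stopping at the first stop codon.

    A trailing incomplete codon is dropped; any codon containing a base other
    than A/C/G/T (e.g. N) yields 'X'.
    """
    peptide = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3].upper()
        if codon in _STOPS:
            break
        aa = _CODON_TO_AA.get(codon)
        peptide.append(aa if aa is not None else "X")
    return "".join(peptide)


def junction_residue_span(n5: int, peptide_len: int) -> tuple[int, int]:
    """1-based peptide positions whose codons touch both partners.

    When the break splits a codon the chimeric residue ``n5 // 3 + 1`` is the
    span; when the break falls exactly between codons the span is the boundary
    residue pair.  The span is clipped to the translated peptide (a stop codon
    can truncate it).
    """
    if n5 % 3 == 0:
        lo, hi = n5 // 3, n5 // 3 + 1
    else:
        lo = hi = n5 // 3 + 1
    lo = max(1, min(lo, peptide_len))
    hi = max(1, min(hi, peptide_len))
    return (lo, hi)


def make_junction_peptide(event: FusionEvent, cds5: str, cds3: str) -> JunctionPeptide:
    """Assemble and translate the junction CDS for one fusion event."""
    in_frame = is_in_frame(event.n5, event.n3off)
    jcds = build_junction_cds(cds5, event.n5, cds3, event.n3off)
    peptide = translate_cds(jcds) if in_frame else ""
    span = junction_residue_span(event.n5, len(peptide)) if peptide else (0, 0)
    return JunctionPeptide(
        fusion_key=event.key,
        junction_cds=jcds,
        peptide=peptide,
        junction_residue_span=span,
        in_frame=in_frame,
        n5=event.n5,
    )


def junction_windows(jp: JunctionPeptide, k: int = 9) -> list[tuple[int, str]]:
    """Tiling k-mers of the junction peptide that overlap the breakpoint.

    Each returned window contains at least one residue encoded on each side of
    the junction; a chimeric codon (break inside a codon) counts for both
    sides.  Out-of-frame events yield an empty list.
    """
    if not jp.in_frame or not jp.peptide:
        return []
    n5 = jp.n5
    L = len(jp.peptide)
    if n5 % 3 == 0:
        last5 = n5 // 3        # last residue wholly encoded by the 5' partner
        first3 = n5 // 3 + 1   # first residue wholly encoded by the 3' partner
    else:
        last5 = first3 = n5 // 3 + 1  # chimeric residue, counted as both sides
    out = []
    for s in range(1, L - k + 2):  # 1-based window starts
        if s <= last5 and s + k - 1 >= first3:
            out.append((s - 1, jp.peptide[s - 1 : s - 1 + k]))
    return out


def junction_contig_name(event: FusionEvent) -> str:
    """Canonical name of the assembled junction contig for one fusion event."""
    return f"ctg:{event.sample}:{event.gene5}-{event.gene3}:{event.bp5}-{event.bp3}"


def fusion_candidates(
    event: FusionEvent, cds5: str, cds3: str, k: int = 9
) -> list[PeptidePrecursor]:
    """Junction nonamer precursors for one fusion event.

    Out-of-frame events and junctions with no translatable overlap (e.g. a
    stop codon immediately after the breakpoint, or a breakpoint retaining no
    5' coding sequence) yield an empty list with a logged reason.
    """
    if event.n5 == 0:
        log.info("%s: no 5' coding sequence retained; no junction peptide", event.key)
        return []
    jp = make_junction_peptide(event, cds5, cds3)
    if not jp.in_frame:
        log.info("%s: out-of-frame junction; excluded", event.key)
        return []
    windows = junction_windows(jp, k)
    if not windows:
        log.info("%s: junction peptide too short for any overlapping %d-mer", event.key, k)
    return [
        PeptidePrecursor(
            sample=event.sample,
            peptide=pep,
            wt_peptide="",
            source="fusion",
            source_key=event.lesion_key,
            window_offset=off,
            scorable=set(pep) <= _AA_SET,
        )
        for off, pep in windows
    ]
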