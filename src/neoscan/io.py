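"""Readers and writers for every external format the pipeline touches.

Conventions at the file boundary:

* variant tables carry 1-based genomic coordinates (converted once on read);
* the transcript table is GenePred-like and carries 0-based half-open exon
  and CDS coordinates, matching the in-memory model directly;
* SAM text is read through pysam and reduced to reference-matching blocks;
* all TSV outputs start with a ``#neoscan`` schema-version comment line.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ParseError, ValidationError
from .models import (
    AlignedRead,
    CandidateEpitope,
    ExpressionCall,
    FusionEvent,
    HlaGenotype,
    MissenseVariant,
    PeptidePrecursor,
    ProteinRecord,
    TranscriptModel,
    allele_locus,
    normalize_allele,
)

log = logging.getLogger(__name__)

SCHEMA_VERSION = "v1"

_AA_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")

VARIANT_COLUMNS = [
    "sample",
    "gene",
    "mrna_accession",
    "protein_gi",
    "mutation_class",
    "amino_acid_change",
    "chrom",
    "pos",
    "ref_allele",
    "mut_allele",
    "mutant_reads_tumor",
    "total_reads_tumor",
    "mutant_reads_normal",
    "total_reads_normal",
]


@dataclass(frozen=True)
class ReadStats:
    """Bookkeeping for a variant-matrix read: rows in = records + skipped + errored."""

    n_rows: int
    n_records: int
    n_skipped: int
    n_errored: int


def _schema_line(kind: str) -> str:
    return f"#neoscan\t{kind}\t{SCHEMA_VERSION}\n"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# variant matrix


def read_variant_matrix(path, errors: str = "raise") -> list[MissenseVariant]:
    """Read the somatic variant data matrix; missense rows only.

    Rows whose ``mutation_class`` is not ``missense`` are skipped with a
    logged count.  With ``errors="raise"`` (default) a malformed amino-acid
    change or an invalid record raises, naming the offending line; with
    ``errors="skip"`` bad rows are counted and dropped.  Use
    :func:`read_variant_matrix_stats` for the bookkeeping counts.
    """
    records, _ = read_variant_matrix_stats(path, errors=errors)
    return records


def read_variant_matrix_stats(
    path, errors: str = "raise"
) -> tuple[list[MissenseVariant], ReadStats]:
    df = _read_tsv(path)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"variant matrix missing columns: {sorted(missing)}")
    records: list[MissenseVariant] = []
    n_skipped = n_errored = 0
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        if row["mutation_class"].strip().lower() != "missense":
            n_skipped += 1
            continue
        try:
            m = _AA_CHANGE_RE.match(row["amino_acid_change"].strip())
            if not m:
                raise ParseError(
                    f"malformed amino-acid change {row['amino_acid_change']!r}", line=lineno
                )
            aa_ref, aa_pos, aa_mut = m.group(1), int(m.group(2)), m.group(3)
            records.append(
                MissenseVariant(
                    sample=row["sample"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref_allele=row["ref_allele"],
                    mut_allele=row["mut_allele"],
                    gene=row["gene"],
                    mrna_accession=row["mrna_accession"],
                    aa_ref=aa_ref,
                    aa_pos=aa_pos,
                    aa_mut=aa_mut,
                    mutation_class="missense",
                    mutant_reads_tumor=int(row["mutant_reads_tumor"]),
                    total_reads_tumor=int(row["total_reads_tumor"]),
                    mutant_reads_normal=int(row["mutant_reads_normal"]),
                    total_reads_normal=int(row["total_reads_normal"]),
                )
            )
        except (ParseError, ValidationError, ValueError) as exc:
            if errors == "raise":
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(str(exc), line=lineno) from exc
            n_errored += 1
            log.warning("variant row %d dropped: %s", lineno, exc)
    if n_skipped:
        log.info("skipped %d non-missense rows", n_skipped)
    stats = ReadStats(
        n_rows=len(df), n_records=len(records), n_skipped=n_skipped, n_errored=n_errored
    )
    return records, stats


def write_variant_matrix(variants: list[MissenseVariant], path) -> None:
    rows = [
        {
            "sample": v.sample,
            "gene": v.gene,
            "mrna_accession": v.mrna_accession,
            "protein_gi": "",
            "mutation_class": v.mutation_class,
            "amino_acid_change": f"{v.aa_ref}{v.aa_pos}{v.aa_mut}",
            "chrom": v.chrom,
            "pos": v.pos,
            "ref_allele": v.ref_allele,
            "mut_allele": v.mut_allele,
            "mutant_reads_tumor": v.mutant_reads_tumor,
            "total_reads_tumor": v.total_reads_tumor,
            "mutant_reads_normal": v.mutant_reads_normal,
            "total_reads_normal": v.total_reads_normal,
        }
        for v in variants
    ]
    with open(path, "w") as fh:
        fh.write(_schema_line("variants"))
        pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HLA genotypes

_OPTITYPE_COLS = ["A1", "A2", "B1", "B2", "C1", "C2"]


def read_hla_calls(path) -> list[HlaGenotype]:
    """Read HLA class I calls from an OptiType-style TSV or a two-column list.

    The OptiType-style table has per-locus columns A1..C2 (extra columns such
    as read counts are ignored); the list form has ``sample`` plus a
    comma-separated ``alleles`` column.  Alleles are normalised to two-field
    ``HLA-A*02:01`` form (higher resolution is truncated with a warning) and
    a locus reporting a single allele is expanded to a homozygous pair.
    """
    df = _read_tsv(path)
    out = []
    if set(_OPTITYPE_COLS) <= set(df.columns):
        sample_col = "sample" if "sample" in df.columns else df.columns[0]
        for _, row in df.iterrows():
            alleles = []
            for locus in ("A", "B", "C"):
                pair = [row[f"{locus}1"].strip(), row[f"{locus}2"].strip()]
                pair = [a for a in pair if a]
                if len(pair) == 0:
                    raise ValidationError(f"{row[sample_col]}: no HLA-{locus} allele reported")
                if len(pair) == 1:
                    pair = pair * 2
                alleles.extend(_normalize_reported(a) for a in pair)
            out.append(HlaGenotype(sample=row[sample_col], alleles=tuple(alleles)))
        return out
    if {"sample", "alleles"} <= set(df.columns):
        for _, row in df.iterrows():
            tokens = [t.strip() for t in row["alleles"].split(",") if t.strip()]
            by_locus: dict[str, list[str]] = {"A": [], "B": [], "C": []}
            for t in tokens:
                a = _normalize_reported(t)
                by_locus[allele_locus(a)].append(a)
            alleles = []
            for locus, found in by_locus.items():
                if len(found) > 2:
                    raise ValidationError(
                        f"{row['sample']}: more than two HLA-{locus} alleles: {found}"
                    )
                if len(found) == 0:
                    raise ValidationError(f"{row['sample']}: no HLA-{locus} allele reported")
                if len(found) == 1:
                    found = found * 2
                alleles.extend(found)
            out.append(HlaGenotype(sample=row["sample"], alleles=tuple(alleles)))
        return out
    raise FormatError(
        "unrecognised HLA call format: need OptiType-style A1..C2 columns "
        "or (sample, alleles) columns"
    )


def _normalize_reported(token: str) -> str:
    normalized = normalize_allele(token)
    # warn when resolution beyond two fields was discarded
    if token.count(":") > 1:
        log.warning("allele %s truncated to two-field %s", token, normalized)
    return normalized


def write_hla_calls(genotypes: list[HlaGenotype], path) -> None:
    rows = []
    for g in genotypes:
        row = {"sample": g.sample}
        for locus in ("A", "B", "C"):
            p = g.locus(locus)
            row[f"{locus}1"], row[f"{locus}2"] = p[0], p[1]
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(_schema_line("hla_calls"))
        pd.DataFrame(rows, columns=["sample", *_OPTITYPE_COLS]).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM


def read_sam_subset(
    path,
    min_mapq: int = 1,
    include_duplicates: bool = False,
    include_secondary: bool = False,
) -> list[AlignedRead]:
    """Read a SAM text file into aligned reads with reference-matching blocks.

    Blocks cover exactly the reference-consuming match ops (M, =, X);
    deletions (D) and splice gaps (N) break blocks.  Unmapped reads are
    dropped; duplicate-marked, secondary and supplementary alignments are
    excluded by default, as are reads below ``min_mapq``.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        try:
            iterator = list(sam.fetch(until_eof=True))
        except OSError as exc:
            raise ParseError(
                f"malformed SAM record in {path} (CIGAR/sequence mismatch?): {exc}"
            ) from exc
        for aln in iterator:
            if aln.is_unmapped:
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            if not include_duplicates and aln.is_duplicate:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            seq = aln.query_sequence
            if seq is None:
                raise ParseError(f"read {aln.query_name} has no sequence")
            blocks = _blocks_from_cigar(aln)
            quals = tuple(aln.query_qualities) if aln.query_qualities is not None else None
            rg = str(aln.get_tag("RG")) if aln.has_tag("RG") else ""
            out.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    blocks=blocks,
                    query_sequence=seq,
                    mapq=aln.mapping_quality,
                    base_qualities=quals,
                    sample=rg,
                )
            )
    return out


_REF_QUERY_OPS = {0, 7, 8}  # M, =, X
_QUERY_ONLY_OPS = {1, 4}  # I, S
_REF_ONLY_OPS = {2, 3}  # D, N


def _blocks_from_cigar(aln) -> tuple[tuple[int, int, int], ...]:
    """Walk the CIGAR, emitting (ref_start, ref_end, query_offset) match blocks."""
    blocks = []
    rpos = aln.reference_start
    qpos = 0
    consumed = 0
    for op, length in aln.cigartuples:
        if op in _REF_QUERY_OPS:
            blocks.append((rpos, rpos + length, qpos))
            rpos += length
            qpos += length
            consumed += length
        elif op in _QUERY_ONLY_OPS:
            qpos += length
            consumed += length
        elif op in _REF_ONLY_OPS:
            rpos += length
        elif op == 5:  # H: consumes neither stored sequence nor reference
            continue
        else:
            raise ParseError(f"read {aln.query_name}: unsupported CIGAR op code {op}")
    if consumed != len(aln.query_sequence):
        raise ParseError(
            f"read {aln.query_name}: CIGAR consumes {consumed} query bases, "
            f"sequence has {len(aln.query_sequence)}"
        )
    return tuple(blocks)


# ---------------------------------------------------------------------------
# fusion events


FUSION_COLUMNS = [
    "sample",
    "gene5",
    "tx5",
    "bp5",
    "gene3",
    "tx3",
    "bp3",
    "n5",
    "n3off",
    "junction_read_count",
]


def read_fusion_table(path) -> list[FusionEvent]:
    """Read fusion events from the BEDPE-like TSV with precomputed coding offsets."""
    df = _read_tsv(path)
    missing = set(FUSION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"fusion table missing columns: {sorted(missing)}")
    return [
        FusionEvent(
            sample=row["sample"],
            gene5=row["gene5"],
            tx5=row["tx5"],
            bp5=int(row["bp5"]),
            gene3=row["gene3"],
            tx3=row["tx3"],
            bp3=int(row["bp3"]),
            n5=int(row["n5"]),
            n3off=int(row["n3off"]),
            junction_read_count=int(row["junction_read_count"]),
        )
        for _, row in df.iterrows()
    ]


def write_fusion_table(events: list[FusionEvent], path) -> None:
    rows = [
        {
            "sample": e.sample,
            "gene5": e.gene5,
            "tx5": e.tx5,
            "bp5": e.bp5,
            "gene3": e.gene3,
            "tx3": e.tx3,
            "bp3": e.bp3,
            "n5": e.n5,
            "n3off": e.n3off,
            "junction_read_count": e.junction_read_count,
        }
        for e in events
    ]
    with open(path, "w") as fh:
        fh.write(_schema_line("fusions"))
        pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(fh, sep="\t", index=False)


def derive_coding_offsets(
    tx5: TranscriptModel, bp5: int, tx3: TranscriptModel, bp3: int
) -> tuple[int, int]:
    """Derive (n5, n3off) from transcript models and genomic breakpoints.

    ``bp5`` is the last retained genomic base of the 5' partner and ``bp3``
    the first retained base of the 3' partner (0-based).  ``n5`` counts coding
    bases of the 5' transcript up to and including ``bp5``; ``n3off`` counts
    coding bases of the 3' transcript strictly before ``bp3``.
    """
    cds5 = tx5.coding_genomic_positions()
    cds3 = tx3.coding_genomic_positions()
    try:
        n5 = cds5.index(bp5) + 1
    except ValueError:
        raise ValidationError(f"{tx5.tx_id}: breakpoint {bp5} is not a coding position")
    try:
        n3off = cds3.index(bp3)
    except ValueError:
        raise ValidationError(f"{tx3.tx_id}: breakpoint {bp3} is not a coding position")
    return n5, n3off


# ---------------------------------------------------------------------------
# transcripts (GenePred-like)

TRANSCRIPT_COLUMNS = [
    "tx_id",
    "gene",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start",
    "cds_end",
]


def read_transcript_models(path) -> list[TranscriptModel]:
    """Read transcript models (0-based half-open exon blocks, GenePred-like)."""
    df = _read_tsv(path)
    missing = set(TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"transcript table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        starts = [int(x) for x in row["exon_starts"].rstrip(",").split(",")]
        ends = [int(x) for x in row["exon_ends"].rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise ParseError(f"{row['tx_id']}: exon start/end count mismatch")
        out.append(
            TranscriptModel(
                tx_id=row["tx_id"],
                gene=row["gene"],
                chrom=row["chrom"],
                strand=row["strand"],
                exons=tuple(zip(starts, ends)),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
            )
        )
    return out


def write_transcript_models(models: list[TranscriptModel], path) -> None:
    rows = [
        {
            "tx_id": t.tx_id,
            "gene": t.gene,
            "chrom": t.chrom,
            "strand": t.strand,
            "exon_starts": ",".join(str(s) for s, _ in t.exons),
            "exon_ends": ",".join(str(e) for _, e in t.exons),
            "cds_start": t.cds_start,
            "cds_end": t.cds_end,
        }
        for t in models
    ]
    with open(path, "w") as fh:
        fh.write(_schema_line("transcripts"))
        pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read proteins; header fields ``gene=`` ``mrna=`` ``gi=`` carry provenance."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        out.append(
            ProteinRecord(
                protein_id=rec.id,
                gene=attrs.get("gene", rec.id),
                sequence=str(rec.seq).upper(),
                mrna_accession=attrs.get("mrna", ""),
                protein_gi=attrs.get("gi", ""),
            )
        )
    return out


def write_protein_fasta(records: list[ProteinRecord], path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.protein_id,
            description=f"gene={r.gene} mrna={r.mrna_accession} gi={r.protein_gi}",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_sequence_fasta(path) -> dict[str, str]:
    """Plain FASTA into an id -> uppercase sequence mapping (CDS, contigs)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sequence_fasta(sequences: dict[str, str], path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(seqs, str(path), "fasta")


def write_peptide_fasta(precursors: list[PeptidePrecursor], path) -> None:
    """Export window peptides for hand-off to an external predictor.

    Headers encode provenance as ``sample|source_key|offset``.
    """
    with open(path, "w") as fh:
        for p in precursors:
            fh.write(f">{p.sample}|{p.source_key}|{p.window_offset}\n{p.peptide}\n")


# ---------------------------------------------------------------------------
# candidates / expression calls

CANDIDATE_COLUMNS = [
    "sample",
    "peptide",
    "wt_peptide",
    "allele",
    "ic50_nM",
    "source",
    "source_key",
    "window_offset",
    "expressed",
]


def write_candidates(candidates: list[CandidateEpitope], path) -> None:
    rows = [
        {
            "sample": c.sample,
            "peptide": c.peptide,
            "wt_peptide": c.wt_peptide,
            "allele": c.allele,
            "ic50_nM": f"{c.ic50_nM:.4f}",
            "source": c.source,
            "source_key": c.source_key,
            "window_offset": c.window_offset,
            "expressed": c.expressed,
        }
        for c in candidates
    ]
    with open(path, "w") as fh:
        fh.write(_schema_line("candidates"))
        pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_candidates(path) -> list[CandidateEpitope]:
    df = _read_tsv(path)
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"candidate table missing columns: {sorted(missing)}")
    return [
        CandidateEpitope(
            sample=row["sample"],
            peptide=row["peptide"],
            wt_peptide=row["wt_peptide"],
            allele=row["allele"],
            ic50_nM=float(row["ic50_nM"]),
            source=row["source"],
            source_key=row["source_key"],
            window_offset=int(row["window_offset"]),
            expressed=row["expressed"],
        )
        for _, row in df.iterrows()
    ]


def write_expression_calls(calls: list[ExpressionCall], path) -> None:
    rows = [
        {
            "candidate_key": c.candidate_key,
            "mutant_read_count": c.mutant_read_count,
            "spanning_mutant_read_count": c.spanning_mutant_read_count,
            "expressed": "yes" if c.expressed else "no",
        }
        for c in calls
    ]
    with open(path, "w") as fh:
        fh.write(_schema_line("expression"))
        pd.DataFrame(
            rows,
            columns=[
                "candidate_key",
                "mutant_read_count",
                "spanning_mutant_read_count",
                "expressed",
            ],
        ).to_csv(fh, sep="\t", index=False)
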