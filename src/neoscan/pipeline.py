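"""End-to-end orchestration: windows -> fusion windows -> binding -> expression -> report.

Every stage is a pure function of its inputs and the run configuration;
re-running the same configuration over the same inputs reproduces
byte-identical outputs.  Samples without RNA-seq get expression state
``unknown`` for all their candidates, never ``no``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as nio
from .binding import (
    DEFAULT_IC50_THRESHOLD_NM,
    MatrixPredictor,
    TablePredictor,
    parse_predictor_table,
    read_matrices,
    score_candidates,
)
from .errors import FormatError, ValidationError
from .expression import call_expression, fusion_window_expression
from .fusion import fusion_candidates, junction_contig_name
from .models import CandidateEpitope, ExpressionCall, SampleSummary
from .peptides import missense_candidates, window_precursors
from .report import (
    cohort_proportions,
    mutation_epitope_regression,
    recurrence_table,
    sample_summary_frame,
    summarize_cohort,
    summarize_sample,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Defaults reproduce the canonical analysis settings: 9-mer windows, an
    inclusive 500 nM IC50 cutoff, and the strict expression rule requiring a
    mutant-supporting read to span the window's full 27 bases.
    """

    proteins: str = ""
    cds: str = ""
    transcripts: str = ""
    variants: str = ""
    fusions: str = ""
    hla: str = ""
    reads: str = ""
    contigs: str = ""
    matrices: str = ""
    predictor_table: str = ""
    samples: str = ""
    outdir: str = "neoscan_out"
    peptide_length: int = 9
    ic50_threshold_nM: float = DEFAULT_IC50_THRESHOLD_NM
    backend: str = "matrix"  # "matrix" | "table"
    strict_mutant_spanning: bool = True
    min_base_quality: int = 20
    min_mapq: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory results of a run (also written to the output directory)."""

    candidates: list[CandidateEpitope]
    expression_calls: list[ExpressionCall]
    summaries: list[SampleSummary]
    cohort_table: pd.DataFrame
    proportions: dict
    recurrence: list
    outdir: str


def _read_sample_meta(path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    need = {"sample", "subtype", "rna_available", "relapse"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"sample metadata missing columns: {sorted(missing)}")
    return [
        {
            "sample": r["sample"],
            "subtype": r["subtype"],
            "rna_available": r["rna_available"].strip().lower() in ("1", "true", "yes"),
            "relapse": r["relapse"].strip().lower() in ("1", "true", "yes"),
        }
        for _, r in df.iterrows()
    ]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the report files to ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    k = config.peptide_length

    # --- inputs -----------------------------------------------------------
    if not config.variants:
        raise ValidationError("stage 'windows' requires a variant table")
    proteins = {p.mrna_accession: p for p in nio.read_protein_fasta(config.proteins)}
    variants = nio.read_variant_matrix(config.variants)
    genotypes = {g.sample: g for g in nio.read_hla_calls(config.hla)}
    transcripts = {t.tx_id: t for t in nio.read_transcript_models(config.transcripts)}
    fusions = nio.read_fusion_table(config.fusions) if config.fusions else []
    cds = nio.read_sequence_fasta(config.cds) if config.cds else {}
    meta = (
        _read_sample_meta(config.samples)
        if config.samples
        else [
            {"sample": s, "subtype": "", "rna_available": bool(config.reads), "relapse": False}
            for s in sorted({v.sample for v in variants} | {f.sample for f in fusions})
        ]
    )
    meta_by_sample = {m["sample"]: m for m in meta}

    if config.backend == "matrix":
        if not config.matrices:
            raise ValidationError("matrix backend requires a matrices file")
        backend = MatrixPredictor(read_matrices(config.matrices))
    elif config.backend == "table":
        if not config.predictor_table:
            raise ValidationError("table backend requires a predictor output file")
        backend = TablePredictor(
            parse_predictor_table(Path(config.predictor_table).read_text())
        )
    else:
        raise ValidationError(f"unknown backend {config.backend!r}")

    reads = nio.read_sam_subset(config.reads, min_mapq=config.min_mapq) if config.reads else []
    reads_by_chrom: dict[str, list] = {}
    for r in reads:
        reads_by_chrom.setdefault(r.chrom, []).append(r)

    # --- windows and binding ---------------------------------------------
    variants_by_key = {(v.sample, v.lesion_key): v for v in variants}
    fusion_by_key: dict[tuple[str, str], object] = {}
    candidates: list[CandidateEpitope] = []
    skipped = {"no_protein": 0, "no_genotype": 0, "no_cds": 0}

    by_sample_precursors: dict[str, list] = {}
    for v in variants:
        protein = proteins.get(v.mrna_accession)
        if protein is None:
            log.warning("%s: no protein record for %s; skipped", v.sample, v.mrna_accession)
            skipped["no_protein"] += 1
            continue
        ws = missense_candidates(protein, v, k=k)
        by_sample_precursors.setdefault(v.sample, []).extend(window_precursors(ws, v))
    for f in fusions:
        fusion_by_key.setdefault((f.sample, f.lesion_key), f)
        cds5, cds3 = cds.get(f.tx5), cds.get(f.tx3)
        if cds5 is None or cds3 is None:
            log.warning("%s: missing CDS for %s or %s; skipped", f.sample, f.tx5, f.tx3)
            skipped["no_cds"] += 1
            continue
        pre = fusion_candidates(f, cds5, cds3, k=k)
        by_sample_precursors.setdefault(f.sample, []).extend(pre)

    for sample in sorted(by_sample_precursors):
        genotype = genotypes.get(sample)
        if genotype is None:
            log.warning("%s: no HLA genotype; sample skipped", sample)
            skipped["no_genotype"] += 1
            continue
        candidates.extend(
            score_candidates(
                by_sample_precursors[sample],
                genotype,
                backend,
                threshold_nM=config.ic50_threshold_nM,
            )
        )
    candidates.sort(
        key=lambda c: (c.sample, c.source, c.source_key, c.window_offset, c.allele)
    )

    # --- expression -------------------------------------------------------
    expression_calls: list[ExpressionCall] = []
    for c in candidates:
        m = meta_by_sample.get(c.sample, {"rna_available": bool(reads)})
        if not m["rna_available"]:
            c.expressed = "unknown"
            continue
        if c.source == "missense":
            v = variants_by_key[(c.sample, c.source_key)]
            tx = transcripts.get(v.mrna_accession)
            if tx is None:
                c.expressed = "unknown"
                continue
            sample_reads = [
                r
                for r in reads_by_chrom.get(v.chrom, [])
                if r.sample in ("", c.sample)
            ]
            call = call_expression(
                c,
                v,
                tx,
                sample_reads,
                k=k,
                strict_mutant_spanning=config.strict_mutant_spanning,
                min_base_quality=config.min_base_quality,
            )
        else:
            event = fusion_by_key.get((c.sample, c.source_key))
            if event is None:
                c.expressed = "unknown"
                continue
            contig = junction_contig_name(event)
            call = fusion_window_expression(c, contig, reads_by_chrom.get(contig, []), k=k)
        expression_calls.append(call)
        c.expressed = "yes" if call.expressed else "no"

    # --- report -----------------------------------------------------------
    summaries = []
    for m in meta:
        s = m["sample"]
        summaries.append(
            summarize_sample(
                [c for c in candidates if c.sample == s],
                [e for e in expression_calls if e.candidate_key.startswith(f"{s}|")],
                [v for v in variants if v.sample == s],
                sample=s,
                subtype=m["subtype"],
                rna_available=m["rna_available"],
                relapse=m["relapse"],
            )
        )
    cohort = summarize_cohort(summaries)
    proportions = cohort_proportions(summaries)
    try:
        slope, intercept, r2 = mutation_epitope_regression(summaries)
        regression = {"slope": slope, "intercept": intercept, "r_squared": r2}
    except ValidationError:
        regression = None
    recurrence = recurrence_table(variants, fusions, candidates)

    # --- outputs ----------------------------------------------------------
    nio.write_candidates(candidates, out / "candidates.tsv")
    nio.write_expression_calls(expression_calls, out / "expression.tsv")
    with open(out / "sample_summary.tsv", "w") as fh:
        fh.write("#neoscan\tsample_summary\tv1\n")
        sample_summary_frame(summaries).to_csv(fh, sep="\t", index=False)
    with open(out / "subtype_summary.tsv", "w") as fh:
        fh.write("#neoscan\tsubtype_summary\tv1\n")
        cohort.to_csv(fh, sep="\t", index=False)
    with open(out / "recurrence.tsv", "w") as fh:
        fh.write("#neoscan\trecurrence\tv1\n")
        pd.DataFrame(
            [
                {
                    "lesion": r.lesion,
                    "n_samples_total": r.n_samples_total,
                    "n_samples_with_epitope": r.n_samples_with_epitope,
                }
                for r in recurrence
            ]
        ).to_csv(fh, sep="\t", index=False)
    cohort_json = {"proportions": proportions, "regression": regression}
    with open(out / "cohort.json", "w") as fh:
        json.dump(cohort_json, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write(f"config_hash\t{config.digest()}\n")
        fh.write(f"n_variants\t{len(variants)}\n")
        fh.write(f"n_fusions\t{len(fusions)}\n")
        fh.write(f"n_candidates\t{len(candidates)}\n")
        fh.write(f"n_expression_calls\t{len(expression_calls)}\n")
        for key, n in sorted(skipped.items()):
            fh.write(f"skipped_{key}\t{n}\n")

    return PipelineResult(
        candidates=candidates,
        expression_calls=expression_calls,
        summaries=summaries,
        cohort_table=cohort,
        proportions=proportions,
        recurrence=recurrence,
        outdir=str(out),
    )
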