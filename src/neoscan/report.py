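"""Per-sample and cohort landscape summaries.

Reporting conventions: percentages are rounded half-up to one decimal (ratios
of magnitude <= 1 to two decimals), per-subtype means to two decimals, and
relapse samples are excluded from the primary averages and shown in a
parenthetical companion column.  "Neoepitope mutations" counts mutations with
at least one passing candidate; peptide-allele pair counts are reported in a
separate column so both readings of "number of neoepitopes" are available.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .models import (
    CandidateEpitope,
    ExpressionCall,
    FusionEvent,
    MissenseVariant,
    RecurrenceSummary,
    SampleSummary,
)

log = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the printed precision (half-up)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 x numerator/denominator, half-up to ``decimals``."""
    if denominator <= 0:
        raise ValidationError("percentage denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, decimals)


def format_ratio(numerator: int, denominator: int, decimals: int = 2) -> float:
    """numerator/denominator as a proportion of magnitude <= 1, half-up."""
    if denominator <= 0:
        raise ValidationError("ratio denominator must be positive")
    return round_half_up(numerator / denominator, decimals)


def dedup_candidates(candidates: list[CandidateEpitope]) -> list[CandidateEpitope]:
    """Collapse to one candidate per (sample, peptide, allele), keeping first provenance."""
    seen = set()
    out = []
    for c in candidates:
        key = (c.sample, c.peptide, c.allele)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def summarize_sample(
    candidates: list[CandidateEpitope],
    expression_calls: list[ExpressionCall],
    variants: list[MissenseVariant],
    sample: str,
    subtype: str = "",
    rna_available: bool = True,
    relapse: bool = False,
) -> SampleSummary:
    """Landscape counts for one sample.

    ``n_candidates`` counts distinct (peptide, allele) pairs; a mutation
    counts toward ``n_neoepitope_mutations`` when at least one of its windows
    passes the binding filter.  Without RNA-seq the expressed count is None
    (unknown), never zero.
    """
    for group, items in (("candidates", candidates), ("variants", variants)):
        bad = {x.sample for x in items} - {sample}
        if bad:
            raise ValidationError(f"{group} from foreign samples {sorted(bad)} for {sample}")

    deduped = dedup_candidates(candidates)
    epitope_lesions = {c.source_key for c in candidates if c.source == "missense"}
    n_neo_mut = sum(1 for v in variants if v.lesion_key in epitope_lesions)

    n_expressed: int | None
    if not rna_available:
        n_expressed = None
    else:
        expressed_keys = {e.candidate_key for e in expression_calls if e.expressed}
        by_key = {c.key: c for c in candidates}
        expressed_pairs = {
            (by_key[k].peptide, by_key[k].allele) for k in expressed_keys if k in by_key
        }
        n_expressed = len(expressed_pairs)

    return SampleSummary(
        sample=sample,
        subtype=subtype,
        n_missense=len(variants),
        n_neoepitope_mutations=n_neo_mut,
        n_candidates=len(deduped),
        n_expressed_candidates=n_expressed,
        rna_available=rna_available,
        relapse=relapse,
    )


def _mean2(values: list[float]) -> float | None:
    if not values:
        return None
    return round_half_up(sum(values) / len(values), 2)


def summarize_cohort(samples: list[SampleSummary]) -> pd.DataFrame:
    """Per-subtype averages in the landscape-table layout.

    Primary averages exclude relapse samples; the ``*_with_relapse`` columns
    give the averages with relapse samples included (the parenthetical
    convention).  Expressed-candidate means are over RNA-evaluable samples.
    """
    if not samples:
        raise ValidationError("cannot summarize an empty cohort")
    rows = []
    subtypes = sorted({s.subtype for s in samples})
    for subtype in subtypes:
        group = [s for s in samples if s.subtype == subtype]
        primary = [s for s in group if not s.relapse]
        expr_primary = [
            s.n_expressed_candidates for s in primary if s.n_expressed_candidates is not None
        ]
        expr_all = [
            s.n_expressed_candidates for s in group if s.n_expressed_candidates is not None
        ]
        rows.append(
            {
                "subtype": subtype,
                "n_samples": len(primary),
                "n_relapse": len(group) - len(primary),
                "mean_mutations": _mean2([s.n_missense for s in primary]),
                "mean_neoepitopes": _mean2([s.n_candidates for s in primary]),
                "mean_expressed_neoepitopes": _mean2(expr_primary),
                "mean_mutations_with_relapse": _mean2([s.n_missense for s in group]),
                "mean_neoepitopes_with_relapse": _mean2([s.n_candidates for s in group]),
                "mean_expressed_neoepitopes_with_relapse": _mean2(expr_all),
            }
        )
    return pd.DataFrame(rows)


def cohort_proportions(samples: list[SampleSummary]) -> dict[str, float]:
    """Overall cohort proportions (primary samples only).

    ``pct_mutations_with_neoepitope`` is the proportion of missense mutations
    with at least one passing candidate; ``pct_samples_with_neoepitope`` the
    proportion of samples with any candidate.
    """
    primary = [s for s in samples if not s.relapse]
    if not primary:
        raise ValidationError("no primary samples")
    total_mut = sum(s.n_missense for s in primary)
    neo_mut = sum(s.n_neoepitope_mutations for s in primary)
    out = {
        "pct_samples_with_neoepitope": format_percent(
            sum(1 for s in primary if s.n_candidates > 0), len(primary)
        ),
    }
    if total_mut > 0:
        out["pct_mutations_with_neoepitope"] = format_percent(neo_mut, total_mut)
    return out


def mutation_epitope_regression(samples: list[SampleSummary]) -> tuple[float, float, float]:
    """OLS of per-sample candidate count on mutation count: (slope, intercept, R2)."""
    pts = [(s.n_missense, s.n_candidates) for s in samples]
    if len(pts) < 3:
        raise ValidationError("regression needs at least 3 samples")
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if len(set(xs)) == 1:
        raise ValidationError("mutation counts have zero variance; regression undefined")
    res = stats.linregress(xs, ys)
    # constant response: the fit explains nothing, R^2 = 0 by convention
    r2 = 0.0 if len(set(ys)) == 1 else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2


def recurrence_table(
    variants: list[MissenseVariant],
    fusions: list[FusionEvent],
    candidates: list[CandidateEpitope],
    min_samples: int = 1,
) -> list[RecurrenceSummary]:
    """Per-lesion carrier counts and epitope-positive carrier counts.

    A lesion is a normalised protein change (gene + p. notation) or a fusion
    gene pair; a sample carrying the lesion on several transcripts counts
    once.  Only lesions carried by at least ``min_samples`` samples are kept.
    """
    carriers: dict[str, set[str]] = {}
    for v in variants:
        carriers.setdefault(v.lesion_key, set()).add(v.sample)
    for f in fusions:
        carriers.setdefault(f.lesion_key, set()).add(f.sample)

    positives: dict[str, set[str]] = {}
    for c in candidates:
        positives.setdefault(c.source_key, set()).add(c.sample)

    out = []
    for lesion in sorted(carriers):
        total = carriers[lesion]
        if len(total) < min_samples:
            continue
        with_epi = positives.get(lesion, set()) & total
        out.append(
            RecurrenceSummary(
                lesion=lesion,
                n_samples_total=len(total),
                n_samples_with_epitope=len(with_epi),
            )
        )
    return out


def sample_summary_frame(samples: list[SampleSummary]) -> pd.DataFrame:
    """Per-sample summary as a tidy frame (the per-sample landscape data)."""
    rows = []
    for s in samples:
        if s.rna_available and s.n_expressed_candidates is not None:
            if s.n_expressed_candidates > s.n_candidates:
                raise ValidationError(f"{s.sample}: expressed exceeds predicted")
        rows.append(
            {
                "sample": s.sample,
                "subtype": s.subtype,
                "relapse": s.relapse,
                "rna_available": s.rna_available,
                "n_missense": s.n_missense,
                "n_neoepitope_mutations": s.n_neoepitope_mutations,
                "n_candidates": s.n_candidates,
                "n_expressed_candidates": (
                    s.n_expressed_candidates if s.n_expressed_candidates is not None else ""
                ),
            }
        )
    return pd.DataFrame(rows)
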