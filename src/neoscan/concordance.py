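"""HLA typing concordance scoring and cohort allele carrier frequencies.

Sequencing-derived HLA class I genotypes are validated against clinical
typing at two-field resolution, counting correct alleles per locus: a
heterozygous truth pair is scored by maximum bipartite matching against the
called pair (0-2, order-independent); a homozygous truth locus scores 2 only
when called homozygous for that allele, 1 when called heterozygous with one
matching allele, else 0.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import ValidationError
from .models import HlaGenotype, LocusConcordance, allele_locus, normalize_allele
from .report import round_half_up

log = logging.getLogger(__name__)

_LOCI = ("A", "B", "C")


def score_locus(truth: tuple[str, str], called: tuple[str, str]) -> int:
    """Number of correct alleles (0-2) for one locus."""
    t1, t2 = (normalize_allele(a) for a in truth)
    c1, c2 = (normalize_allele(a) for a in called)
    loci = {allele_locus(a) for a in (t1, t2, c1, c2)}
    if len(loci) != 1:
        raise ValidationError(f"alleles span multiple loci: {sorted(loci)}")

    if t1 == t2:  # homozygous truth
        if c1 == c2:
            return 2 if c1 == t1 else 0
        return 1 if t1 in (c1, c2) else 0

    # heterozygous truth: maximum matching; each called allele credits at most
    # one truth allele (identity matching, so the two orientations suffice)
    direct = (t1 == c1) + (t2 == c2)
    crossed = (t1 == c2) + (t2 == c1)
    return max(direct, crossed)


def sample_concordance(truth: HlaGenotype, called: HlaGenotype) -> list[LocusConcordance]:
    """Score all three class I loci of one sample."""
    if truth.sample != called.sample:
        raise ValidationError(
            f"genotypes belong to different samples: {truth.sample} vs {called.sample}"
        )
    out = []
    for locus in _LOCI:
        tp, cp = truth.locus(locus), called.locus(locus)
        out.append(
            LocusConcordance(
                sample=truth.sample,
                locus=locus,
                correct_alleles=score_locus(tp, cp),
                truth_pair=tp,
                called_pair=cp,
            )
        )
    return out


def cohort_accuracy(records: list[LocusConcordance]) -> float:
    """Overall typing accuracy: 100 x correct alleles / (2 x loci scored), 1 decimal."""
    if not records:
        raise ValidationError("cannot compute accuracy of an empty concordance set")
    correct = sum(r.correct_alleles for r in records)
    total = 2 * len(records)
    return round_half_up(100.0 * correct / total, 1)


def carrier_frequencies(genotypes: list[HlaGenotype]) -> pd.DataFrame:
    """Per-allele carrier counts and percentages across a cohort.

    A sample carrying an allele on one or both chromosomes counts once;
    percentages are of cohort size, rounded half-up to one decimal.
    """
    if not genotypes:
        raise ValidationError("cannot compute carrier frequencies of an empty cohort")
    n = len(genotypes)
    carriers: dict[str, int] = {}
    for g in genotypes:
        for allele in set(g.alleles):
            carriers[allele] = carriers.get(allele, 0) + 1
    rows = [
        {
            "allele": allele,
            "locus": allele_locus(allele),
            "carriers": count,
            "percent": round_half_up(100.0 * count / n, 1),
        }
        for allele, count in carriers.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["locus", "carriers", "allele"], ascending=[True, False, True]
    )
    return df.reset_index(drop=True)


def concordance_report(records: list[LocusConcordance]) -> pd.DataFrame:
    """Tidy per-sample, per-locus concordance table with a cohort accuracy line."""
    rows = [
        {
            "sample": r.sample,
            "locus": r.locus,
            "truth": "/".join(r.truth_pair),
            "called": "/".join(r.called_pair),
            "correct_alleles": r.correct_alleles,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
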