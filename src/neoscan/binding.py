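"""MHC class I binding prediction: predictor contract, matrix scorer, IC50 filter.

Binding affinity is expressed as IC50 in nM; lower is stronger, and the
selection rule keeps peptides with predicted IC50 <= 500 nM (inclusive), the
conventional moderate-to-high-affinity cutoff.  Real-world runs use an
external consensus predictor; its tabular output is ingested through
:func:`parse_predictor_table`.  For fully self-contained runs the package
ships a deterministic position-weight-matrix scorer whose normalised score
``s`` maps to nM via the community-standard transform ``IC50 = 50000**(1-s)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .models import (
    RESIDUES,
    CandidateEpitope,
    HlaGenotype,
    PeptidePrecursor,
    normalize_allele,
)

log = logging.getLogger(__name__)

DEFAULT_IC50_THRESHOLD_NM = 500.0
MAX_IC50_NM = 50000.0
_RES_INDEX = {aa: i for i, aa in enumerate(RESIDUES)}


@dataclass(frozen=True)
class BindingScore:
    """Predicted affinity of one peptide for one HLA allele."""

    peptide: str
    allele: str
    ic50_nM: float
    predictor_tag: str = ""

    def __post_init__(self):
        if self.ic50_nM <= 0:
            raise ValidationError(f"{self.peptide}/{self.allele}: IC50 must be positive")


@dataclass(frozen=True)
class ScoringMatrix:
    """A 9 x 20 position-specific residue weight table for one allele.

    Weights lie in [0, 1]; a peptide's score is the mean of its per-position
    weights and maps to IC50 via ``50000**(1 - score)``.
    """

    allele: str
    weights: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape[1] != len(RESIDUES):
            raise ValidationError(f"{self.allele}: matrix must have {len(RESIDUES)} residue columns")
        if not np.isfinite(w).all():
            raise ValidationError(f"{self.allele}: matrix weights must be finite")

    @property
    def k(self) -> int:
        return len(self.weights)


def matrix_score(peptide: str, m: ScoringMatrix) -> BindingScore:
    """Score a peptide against a position weight matrix, as IC50 in nM."""
    if len(peptide) != m.k:
        raise ValidationError(
            f"peptide {peptide!r} has length {len(peptide)}, matrix expects {m.k}"
        )
    if not set(peptide) <= set(RESIDUES):
        raise ValidationError(f"peptide {peptide!r} contains non-scorable residues")
    s = float(np.mean([m.weights[i][_RES_INDEX[aa]] for i, aa in enumerate(peptide)]))
    return BindingScore(
        peptide=peptide,
        allele=m.allele,
        ic50_nM=MAX_IC50_NM ** (1.0 - s),
        predictor_tag="matrix",
    )


def filter_binders(
    scores: list[BindingScore], threshold_nM: float = DEFAULT_IC50_THRESHOLD_NM
) -> list[BindingScore]:
    """Keep scores with IC50 <= threshold (inclusive), preserving input order."""
    if threshold_nM <= 0:
        raise ValidationError("IC50 threshold must be positive")
    return [s for s in scores if s.ic50_nM <= threshold_nM]


_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]{8,15}$")
_ALLELE_TOKEN_RE = re.compile(r"^(?:HLA-)?[ABC]\*?\d{1,3}:\d{1,3}(?::\d+)*[A-Z]?$")
_NUM_RE = re.compile(r"^\d+(\.\d+)?$")


def parse_predictor_table(text: str, predictor_tag: str = "external") -> list[BindingScore]:
    """Parse whitespace-delimited predictor output into binding scores.

    Each data row must contain an HLA allele token, a peptide token and a
    numeric affinity in nM (the last numeric field on the row).  Comment,
    header and decoration lines (no allele+peptide pair) are skipped silently.
    Allele spellings are normalised (e.g. ``HLA-A02:01`` -> ``HLA-A*02:01``).
    """
    scores = []
    saw_data_shape = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or set(line) <= {"-", "="}:
            continue
        tokens = line.split()
        allele = next((t for t in tokens if _ALLELE_TOKEN_RE.match(t)), None)
        peptide = next((t for t in tokens if _PEPTIDE_RE.match(t)), None)
        if allele is None or peptide is None:
            continue  # decoration (header/footer) line
        saw_data_shape = True
        # the affinity column follows the peptide/allele columns; a leading
        # position index must not be mistaken for it
        anchor = max(tokens.index(allele), tokens.index(peptide))
        numeric = [t for t in tokens[anchor + 1 :] if _NUM_RE.match(t)]
        if not numeric:
            raise ParseError(
                f"no numeric affinity field on row for {peptide}/{allele}", line=lineno
            )
        try:
            affinity = float(numeric[-1])
        except ValueError as exc:  # pragma: no cover - _NUM_RE guards this
            raise ParseError(f"non-numeric affinity {numeric[-1]!r}", line=lineno) from exc
        scores.append(
            BindingScore(
                peptide=peptide,
                allele=normalize_allele(allele),
                ic50_nM=affinity,
                predictor_tag=predictor_tag,
            )
        )
    if not saw_data_shape and text.strip():
        raise FormatError("no rows with peptide, allele and affinity columns found")
    return scores


class MatrixPredictor:
    """Deterministic built-in predictor backed by per-allele scoring matrices."""

    def __init__(self, matrices: dict[str, ScoringMatrix]):
        self.matrices = {normalize_allele(a): m for a, m in matrices.items()}

    def supports(self, allele: str) -> bool:
        return normalize_allele(allele) in self.matrices

    def score(self, peptide: str, allele: str) -> float | None:
        m = self.matrices.get(normalize_allele(allele))
        if m is None:
            return None
        return matrix_score(peptide, m).ic50_nM


class TablePredictor:
    """Predictor backed by a previously parsed external output table."""

    def __init__(self, scores: list[BindingScore]):
        self._table = {(s.peptide, s.allele): s.ic50_nM for s in scores}
        self._alleles = {s.allele for s in scores}

    def supports(self, allele: str) -> bool:
        return normalize_allele(allele) in self._alleles

    def score(self, peptide: str, allele: str) -> float | None:
        return self._table.get((peptide, normalize_allele(allele)))


def score_candidates(
    precursors: list[PeptidePrecursor],
    genotype: HlaGenotype,
    backend,
    threshold_nM: float = DEFAULT_IC50_THRESHOLD_NM,
) -> list[CandidateEpitope]:
    """Score every precursor against the sample's distinct alleles and filter.

    Each unique (peptide, allele) pair is scored once (a homozygous locus does
    not double-score); every precursor passing the IC50 filter yields one
    :class:`CandidateEpitope` so that distinct registers and source lesions
    stay separately reported.  Alleles the backend cannot score are logged and
    skipped, never silently scored.
    """
    alleles = genotype.distinct_alleles()
    usable = []
    for allele in alleles:
        if backend.supports(allele):
            usable.append(allele)
        else:
            log.warning("%s: no predictor support for %s; skipped", genotype.sample, allele)

    cache: dict[tuple[str, str], float | None] = {}
    out: list[CandidateEpitope] = []
    for pre in precursors:
        if pre.sample != genotype.sample:
            raise ValidationError(
                f"precursor sample {pre.sample} does not match genotype {genotype.sample}"
            )
        if not pre.scorable:
            log.info("%s: window %s not scorable; skipped", pre.sample, pre.peptide)
            continue
        for allele in usable:
            key = (pre.peptide, allele)
            if key not in cache:
                cache[key] = backend.score(pre.peptide, allele)
            ic50 = cache[key]
            if ic50 is None:
                log.warning("%s: %s/%s not scored by backend", pre.sample, pre.peptide, allele)
                continue
            if ic50 <= threshold_nM:
                out.append(
                    CandidateEpitope(
                        sample=pre.sample,
                        peptide=pre.peptide,
                        wt_peptide=pre.wt_peptide,
                        allele=allele,
                        ic50_nM=ic50,
                        source=pre.source,
                        source_key=pre.source_key,
                        window_offset=pre.window_offset,
                    )
                )
    return out


def render_predictor_table(scores: list[BindingScore]) -> str:
    """Render scores in the whitespace-table shape ingested by the parser."""
    lines = [
        "# predicted MHC class I binding affinities",
        f"{'pos':>4} {'allele':<12} {'peptide':<12} {'affinity_nM':>12}",
        "-" * 44,
    ]
    for i, s in enumerate(scores):
        lines.append(f"{i:>4} {s.allele:<12} {s.peptide:<12} {s.ic50_nM:>12.4f}")
    lines.append("-" * 44)
    return "\n".join(lines) + "\n"


def write_matrices(matrices: dict[str, ScoringMatrix], path) -> None:
    """Write per-allele scoring matrices as a long-form TSV."""
    rows = []
    for allele in sorted(matrices):
        m = matrices[allele]
        for pos in range(m.k):
            row = {"allele": allele, "position": pos + 1}
            row.update({aa: m.weights[pos][j] for j, aa in enumerate(RESIDUES)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_matrices(path) -> dict[str, ScoringMatrix]:
    """Read scoring matrices written by :func:`write_matrices`."""
    df = pd.read_csv(path, sep="\t")
    missing = {"allele", "position", *RESIDUES} - set(df.columns)
    if missing:
        raise FormatError(f"matrix file missing columns: {sorted(missing)}")
    out = {}
    for allele, sub in df.groupby("allele", sort=True):
        sub = sub.sort_values("position")
        weights = tuple(tuple(float(r[aa]) for aa in RESIDUES) for _, r in sub.iterrows())
        out[str(allele)] = ScoringMatrix(allele=str(allele), weights=weights)
    return out
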