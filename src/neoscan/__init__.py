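"""neoscan: neoepitope discovery from somatic missense mutations and gene fusions.

The pipeline generates mutant tiling nonamers around each missense mutation
and across each in-frame fusion junction, filters them by predicted MHC
class I binding (IC50 <= 500 nM), attaches RNA-seq expression evidence (a
mutant-supporting read must span the full 27 bases encoding the nonamer),
scores HLA-typing concordance, and aggregates per-sample and cohort
landscape summaries.
"""

from .binding import (
    BindingScore,
    MatrixPredictor,
    ScoringMatrix,
    TablePredictor,
    filter_binders,
    matrix_score,
    parse_predictor_table,
    score_candidates,
)
from .concordance import carrier_frequencies, cohort_accuracy, sample_concordance, score_locus
from .errors import (
    FormatError,
    InfeasiblePlantError,
    NeoscanError,
    ParseError,
    ValidationError,
)
from .expression import (
    call_expression,
    fusion_window_expression,
    read_spans_window,
    read_supports_mutant,
    window_genomic_positions,
)
from .fusion import (
    build_junction_cds,
    fusion_candidates,
    is_in_frame,
    junction_windows,
    make_junction_peptide,
    translate_cds,
)
from .models import (
    AlignedRead,
    CandidateEpitope,
    ExpressionCall,
    FusionEvent,
    HlaGenotype,
    JunctionPeptide,
    LocusConcordance,
    MissenseVariant,
    PeptidePrecursor,
    ProteinRecord,
    RecurrenceSummary,
    SampleSummary,
    TranscriptModel,
    WindowSet,
    normalize_allele,
)
from .peptides import apply_missense, missense_candidates, tiling_windows, window_precursors
from .pipeline import PipelineResult, RunConfig, run_pipeline
from .report import (
    cohort_proportions,
    format_percent,
    format_ratio,
    mutation_epitope_regression,
    recurrence_table,
    summarize_cohort,
    summarize_sample,
)
from .simulate import FixtureBundle, make_bundle, make_concordance_cohort, write_bundle

__version__ = "0.1.0"
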