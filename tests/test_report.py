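"""Landscape reporting: percentages, per-sample and cohort summaries, regression."""

import pytest

from neoscan.errors import ValidationError
from neoscan.models import (
    CandidateEpitope,
    ExpressionCall,
    FusionEvent,
    MissenseVariant,
    SampleSummary,
)
from neoscan.report import (
    cohort_proportions,
    dedup_candidates,
    format_percent,
    format_ratio,
    mutation_epitope_regression,
    recurrence_table,
    round_half_up,
    summarize_cohort,
    summarize_sample,
)


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (441, 1180, 1, 37.4),
            (2336, 5619, 1, 41.6),
            (2797, 7290, 1, 38.4),
            (11959, 33853, 1, 35.3),
            (212, 540, 1, 39.3),
            (146, 540, 1, 27.0),
            (32, 47, 0, 68.0),
            (0, 10, 1, 0.0),
        ],
    )
    def test_percent_convention(self, num, den, decimals, expected):
        assert format_percent(num, den, decimals) == expected

    def test_proportion_convention(self):
        assert format_ratio(14753, 36284) == 0.41

    def test_half_up_ties(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(2.345, 2) == 2.35

    def test_zero_denominator(self):
        with pytest.raises(ValidationError):
            format_percent(1, 0)


def _variant(sample, gene, aa_pos=20):
    return MissenseVariant(
        sample=sample,
        chrom="c",
        pos=100,
        ref_allele="A",
        mut_allele="T",
        gene=gene,
        mrna_accession=f"{gene}_T",
        aa_ref="K",
        aa_pos=aa_pos,
        aa_mut="M",
    )


def _candidate(sample, peptide, allele, source_key, offset=0, source="missense"):
    return CandidateEpitope(
        sample=sample,
        peptide=peptide,
        wt_peptide=("K" + peptide[1:]) if source == "missense" else "",
        allele=allele,
        ic50_nM=100.0,
        source=source,
        source_key=source_key,
        window_offset=offset,
    )


class TestSummarizeSample:
    def test_three_windows_on_two_alleles_counts_six_pairs(self):
        v = _variant("S1", "G1")
        cands = [
            _candidate("S1", pep, allele, v.lesion_key, off)
            for off, pep in enumerate(["MCDEFGHIK", "MDEFGHIKL", "MEFGHIKLM"])
            for allele in ("HLA-A*02:01", "HLA-B*07:02")
        ]
        s = summarize_sample(cands, [], [v], sample="S1")
        assert (s.n_missense, s.n_neoepitope_mutations, s.n_candidates) == (1, 1, 6)

    def test_zero_candidates(self):
        s = summarize_sample([], [], [_variant("S1", "G1")], sample="S1")
        assert (s.n_neoepitope_mutations, s.n_candidates, s.n_expressed_candidates) == (0, 0, 0)

    def test_without_rna_expression_is_unknown_not_zero(self):
        s = summarize_sample([], [], [_variant("S1", "G1")], sample="S1", rna_available=False)
        assert s.n_expressed_candidates is None

    def test_mixed_sample_input_rejected(self):
        with pytest.raises(ValidationError):
            summarize_sample([], [], [_variant("S2", "G1")], sample="S1")

    def test_expressed_counts_follow_calls(self):
        v = _variant("S1", "G1")
        c1 = _candidate("S1", "MCDEFGHIK", "HLA-A*02:01", v.lesion_key, 0)
        c2 = _candidate("S1", "MDEFGHIKL", "HLA-A*02:01", v.lesion_key, 1)
        calls = [
            ExpressionCall(c1.key, 3, 2, True),
            ExpressionCall(c2.key, 3, 0, False),
        ]
        s = summarize_sample([c1, c2], calls, [v], sample="S1")
        assert s.n_expressed_candidates == 1
        assert s.n_expressed_candidates <= s.n_candidates


class TestDedup:
    def test_same_peptide_allele_from_two_transcripts_counted_once(self):
        c1 = _candidate("S1", "MCDEFGHIK", "HLA-A*02:01", "G1:p.K20M")
        c2 = _candidate("S1", "MCDEFGHIK", "HLA-A*02:01", "G1:p.K20M", offset=3)
        assert len(dedup_candidates([c1, c2])) == 1


def _summary(sample, subtype, n_mut, n_cand, n_expr=None, relapse=False, rna=True):
    return SampleSummary(
        sample=sample,
        subtype=subtype,
        n_missense=n_mut,
        n_neoepitope_mutations=min(n_mut, n_cand),
        n_candidates=n_cand,
        n_expressed_candidates=n_expr,
        rna_available=rna,
        relapse=relapse,
    )


class TestSummarizeCohort:
    def test_single_sample_averages_equal_counts(self):
        df = summarize_cohort([_summary("s1", "BALL", 10, 4, 2)])
        row = df.iloc[0]
        assert (row.mean_mutations, row.mean_neoepitopes, row.mean_expressed_neoepitopes) == (
            10.0,
            4.0,
            2.0,
        )

    def test_known_truth_means(self):
        samples = [
            _summary("s1", "BALL", 10, 4, 2),
            _summary("s2", "BALL", 13, 5, 1),
            _summary("s3", "HGG", 7, 3, 0),
        ]
        df = summarize_cohort(samples).set_index("subtype")
        assert df.loc["BALL"].mean_mutations == 11.5
        assert df.loc["BALL"].mean_neoepitopes == 4.5
        assert df.loc["HGG"].mean_mutations == 7.0

    def test_relapse_only_moves_parenthetical_column(self):
        base = [
            _summary("s1", "BALL", 10, 4, 2),
            _summary("s2", "BALL", 12, 6, 2),
        ]
        with_relapse = base + [_summary("s3", "BALL", 30, 20, 9, relapse=True)]
        df0 = summarize_cohort(base).iloc[0]
        df1 = summarize_cohort(with_relapse).iloc[0]
        assert df1.mean_mutations == df0.mean_mutations  # primary column unchanged
        assert df1.mean_mutations_with_relapse != df0.mean_mutations
        assert df1.n_relapse == 1


class TestRegression:
    def test_collinear_points_r2_one(self):
        samples = [_summary(f"s{i}", "X", i, 2 * i + 1) for i in range(1, 6)]
        slope, intercept, r2 = mutation_epitope_regression(samples)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_response_r2_zero(self):
        samples = [_summary(f"s{i}", "X", i, 5) for i in range(1, 6)]
        _, _, r2 = mutation_epitope_regression(samples)
        assert r2 == pytest.approx(0.0)

    def test_five_point_closed_form(self):
        xs = [1, 2, 4, 5, 7]
        ys = [2, 3, 5, 9, 11]
        samples = [_summary(f"s{i}", "X", x, y) for i, (x, y) in enumerate(zip(xs, ys))]
        n = len(xs)
        sx, sy = sum(xs), sum(ys)
        sxx = sum(x * x for x in xs)
        sxy = sum(x * y for x, y in zip(xs, ys))
        slope_cf = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept_cf = (sy - slope_cf * sx) / n
        ss_res = sum((y - (slope_cf * x + intercept_cf)) ** 2 for x, y in zip(xs, ys))
        ss_tot = sum((y - sy / n) ** 2 for y in ys)
        r2_cf = 1 - ss_res / ss_tot
        assert mutation_epitope_regression(samples) == pytest.approx(
            (slope_cf, intercept_cf, r2_cf)
        )

    def test_zero_variance_rejected(self):
        samples = [_summary(f"s{i}", "X", 5, i) for i in range(4)]
        with pytest.raises(ValidationError):
            mutation_epitope_regression(samples)


class TestRecurrence:
    def _fusion(self, sample):
        return FusionEvent(sample, "ETV6", "ETV6_T", 10, "RUNX1", "RUNX1_T", 20, 30, 0, 5)

    def test_printed_style_fraction(self):
        fusions = [self._fusion(f"s{i}") for i in range(47)]
        cands = [
            _candidate(f"s{i}", "ACDEFGHIK", "HLA-A*02:01", "ETV6-RUNX1", source="fusion")
            for i in range(32)
        ]
        (rec,) = recurrence_table([], fusions, cands)
        assert (rec.n_samples_total, rec.n_samples_with_epitope) == (47, 32)
        assert format_percent(rec.n_samples_with_epitope, rec.n_samples_total, 0) == 68.0

    def test_lesion_without_positives(self):
        fusions = [self._fusion("s1"), self._fusion("s2")]
        (rec,) = recurrence_table([], fusions, [])
        assert (rec.n_samples_total, rec.n_samples_with_epitope) == (2, 0)

    def test_two_transcripts_of_same_lesion_counted_once(self):
        v1 = _variant("s1", "KRAS")
        v2 = MissenseVariant(
            sample="s1",
            chrom="c",
            pos=100,
            ref_allele="A",
            mut_allele="T",
            gene="KRAS",
            mrna_accession="KRAS_T2",
            aa_ref="K",
            aa_pos=20,
            aa_mut="M",
        )
        (rec,) = recurrence_table([v1, v2], [], [])
        assert rec.n_samples_total == 1


class TestCohortProportions:
    def test_pipeline_proportion_equals_percent_of_sums(self):
        samples = [
            _summary("s1", "X", 10, 4),
            _summary("s2", "X", 5, 0),
            _summary("s3", "X", 10, 7),
        ]
        props = cohort_proportions(samples)
        total_neo = sum(s.n_neoepitope_mutations for s in samples)
        total_mut = sum(s.n_missense for s in samples)
        assert props["pct_mutations_with_neoepitope"] == format_percent(total_neo, total_mut)
        assert props["pct_samples_with_neoepitope"] == format_percent(2, 3)
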