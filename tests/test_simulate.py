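"""The synthetic-fixture generator: determinism, internal consistency, planted truth."""

import numpy as np
import pytest

from neoscan.binding import MatrixPredictor, matrix_score, parse_predictor_table, render_predictor_table
from neoscan.errors import InfeasiblePlantError
from neoscan.fusion import translate_cds
from neoscan.simulate import (
    GeneFixture,
    make_binding_world,
    make_bundle,
    make_fusion_case,
    make_gene,
    make_missense_case,
    make_reference,
    reverse_complement,
    write_bundle,
)


def read_dir_bytes(d):
    import pathlib

    return {
        p.name: p.read_bytes() for p in sorted(pathlib.Path(d).iterdir()) if p.is_file()
    }


class TestReference:
    def test_same_seed_identical_bytes(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(make_bundle(seed=11, n_samples=4), d1)
        write_bundle(make_bundle(seed=11, n_samples=4), d2)
        assert read_dir_bytes(d1) == read_dir_bytes(d2)

    def test_cds_translations_match_translate_cds(self):
        genes = make_reference(seed=5)
        for fx in genes.values():
            assert translate_cds(fx.cds) == fx.protein.sequence

    def test_minus_strand_round_trips_through_genome(self):
        """Extracting the coding bases from the chromosome along the transcript
        model and reverse-complement logic must reproduce the CDS."""
        genes = make_reference(seed=5)
        for fx in genes.values():
            tx = fx.transcript
            pos = tx.coding_genomic_positions()
            if tx.strand == "+":
                extracted = "".join(fx.chrom_seq[p] for p in pos)
            else:
                plus = "".join(fx.chrom_seq[p] for p in sorted(pos))
                extracted = reverse_complement(plus)
            assert extracted == fx.cds

    def test_fixed_hotspot_fragments_present(self):
        genes = make_reference(seed=1)
        assert genes["KRAS"].protein.sequence.startswith("MTEYKLVVVGAGG")
        assert genes["HIST1H3B"].protein.sequence[26] == "K"
        assert genes["H3F3A"].protein.sequence[30] == "S"


class TestMissenseCase:
    def _gene(self, seed=3, **kw):
        return make_gene(np.random.default_rng(seed), "G1", aa_length=40, **kw)

    def test_interior_case_has_nine_windows(self):
        case = make_missense_case(np.random.default_rng(0), "S1", self._gene(), "interior")
        assert len(case.windows) == 9
        mut_idx0 = case.variant.aa_pos - case.context_start  # within the context
        for off, mut, wt in case.windows:
            assert mut[mut_idx0 - off] == case.variant.aa_mut
            assert wt[mut_idx0 - off] == case.variant.aa_ref

    def test_edge_case_has_fewer_windows(self):
        case = make_missense_case(np.random.default_rng(0), "S1", self._gene(), "edge")
        assert 1 <= len(case.windows) < 9
        assert case.variant.aa_pos in (1, 40)

    def test_expressed_case_reads_span_and_support(self):
        from neoscan.expression import read_spans_window, read_supports_mutant, window_genomic_positions
        from neoscan import io as nio

        fx = self._gene(n_exons=2)
        case = make_missense_case(np.random.default_rng(1), "S1", fx, "interior", "expressed")
        sam = "@HD\tVN:1.6\n@SQ\tSN:%s\tLN:%d\n" % (fx.transcript.chrom, len(fx.chrom_seq))
        sam += "".join(l + "\n" for l in case.sam_lines)
        p_sam = None
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as d:
            p_sam = pathlib.Path(d) / "r.sam"
            p_sam.write_text(sam)
            reads = nio.read_sam_subset(p_sam)
        mut = [r for r in reads if read_supports_mutant(r, case.variant)]
        assert len(mut) == 2  # two mutant reads, one wild-type
        for off, _, _ in case.windows:
            positions = window_genomic_positions(
                fx.transcript, case.context_start + off, 9
            )
            assert any(read_spans_window(r, positions) for r in mut)

    def test_silent_case_reads_cover_site_but_never_27(self):
        from neoscan.expression import read_spans_window, window_genomic_positions
        from neoscan import io as nio
        import tempfile, pathlib

        fx = self._gene()
        case = make_missense_case(np.random.default_rng(2), "S1", fx, "interior", "silent")
        sam = "@HD\tVN:1.6\n@SQ\tSN:%s\tLN:%d\n" % (fx.transcript.chrom, len(fx.chrom_seq))
        sam += "".join(l + "\n" for l in case.sam_lines)
        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "r.sam"
            p.write_text(sam)
            reads = nio.read_sam_subset(p)
        assert reads and all(r.covers(case.variant.pos0) for r in reads)
        for off, _, _ in case.windows:
            positions = window_genomic_positions(fx.transcript, case.context_start + off, 9)
            assert not any(read_spans_window(r, positions) for r in reads)


class TestFusionCase:
    def _genes(self, seed=7):
        rng = np.random.default_rng(seed)
        return make_gene(rng, "F5", aa_length=40), make_gene(rng, "F3", aa_length=40)

    def test_in_frame_mid_junction_gives_eight_windows(self):
        fx5, fx3 = self._genes()
        case = make_fusion_case(np.random.default_rng(0), "S1", fx5, fx3, in_frame=True)
        assert len(case.windows) == 8

    def test_out_of_frame_gives_none(self):
        fx5, fx3 = self._genes()
        case = make_fusion_case(np.random.default_rng(0), "S1", fx5, fx3, in_frame=False)
        assert case.windows == []

    def test_windows_overlap_junction_in_contig_coordinates(self):
        fx5, fx3 = self._genes()
        case = make_fusion_case(np.random.default_rng(3), "S1", fx5, fx3, in_frame=True)
        n5 = case.event.n5
        for off, pep in case.windows:
            start_nt, end_nt = 3 * off, 3 * off + 27
            assert start_nt < n5 < end_nt


class TestBindingWorld:
    ALLELES = ["HLA-A*02:01", "HLA-A*11:01"]

    def test_planted_pair_passes_and_only_it(self):
        peps = ["VVGAGDVGK", "ACDEFGHIK", "WWWWWWWWW"]
        m = make_binding_world(self.ALLELES, {"HLA-A*11:01": {"VVGAGDVGK"}}, universe=peps)
        pred = MatrixPredictor(m)
        assert pred.score("VVGAGDVGK", "HLA-A*11:01") <= 500
        assert pred.score("ACDEFGHIK", "HLA-A*11:01") > 500
        assert pred.score("VVGAGDVGK", "HLA-A*02:01") > 500

    def test_no_plants_means_no_binders(self):
        m = make_binding_world(self.ALLELES, {})
        pred = MatrixPredictor(m)
        assert pred.score("ACDEFGHIK", "HLA-A*02:01") == 50000.0

    def test_conflicting_universe_peptide_raises(self):
        # a universe peptide sharing 5 of 9 positions with the plant would pass
        near = "VVGAGDVAA"  # differs from the plant at only two positions
        with pytest.raises(InfeasiblePlantError):
            make_binding_world(
                self.ALLELES, {"HLA-A*11:01": {"VVGAGDVGK"}}, universe=[near]
            )

    def test_rendered_table_parses_back_to_matrix_scores(self):
        m = make_binding_world(self.ALLELES, {"HLA-A*11:01": {"VVGAGDVGK"}})
        scores = [
            matrix_score(p, m[a])
            for a in self.ALLELES
            for p in ["VVGAGDVGK", "ACDEFGHIK"]
        ]
        parsed = parse_predictor_table(render_predictor_table(scores))
        assert [(s.peptide, s.allele) for s in parsed] == [
            (s.peptide, s.allele) for s in scores
        ]
        for a, b in zip(scores, parsed):
            assert b.ic50_nM == pytest.approx(a.ic50_nM, rel=1e-6)


class TestBundleTruth:
    def test_truth_consistent_with_inputs(self, bundle):
        samples = {m["sample"] for m in bundle.sample_meta}
        for t in bundle.truth["candidates"]:
            assert t["sample"] in samples
            assert len(t["peptide"]) == 9
        for sample, counts in bundle.truth["samples"].items():
            assert counts["n_neoepitope_mutations"] <= counts["n_missense"]
            if counts["n_expressed_candidates"] is not None:
                assert counts["n_expressed_candidates"] <= counts["n_candidates"]

    def test_interior_variants_have_nine_truth_windows(self, bundle):
        for key, windows in bundle.truth["windows"].items():
            assert 1 <= len(windows) <= 9
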