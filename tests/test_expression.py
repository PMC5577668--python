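"""Codon-to-genome mapping, mutant read support and the 27-base span rule."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from neoscan.errors import ValidationError
from neoscan.expression import (
    call_expression,
    fusion_window_expression,
    read_spans_window,
    read_supports_mutant,
    window_genomic_positions,
)
from neoscan.models import (
    AlignedRead,
    CandidateEpitope,
    MissenseVariant,
    TranscriptModel,
)
from neoscan.simulate import reverse_complement


def simple_read(start, length, chrom="c", seq=None, read_id="r"):
    seq = seq or "A" * length
    return AlignedRead(read_id, chrom, start, ((start, start + length, 0),), seq)


def single_exon_tx(n_codons=20, strand="+", start=100):
    L = 3 * n_codons
    return TranscriptModel(
        "T", "G", "c", strand, ((start, start + L),), start, start + L
    )


class TestWindowGenomicPositions:
    def test_single_exon_window_is_contiguous_27(self):
        tx = single_exon_tx()
        pos = window_genomic_positions(tx, 1, 9)
        assert pos == list(range(100, 127))

    def test_exon_junction_split_sums_to_27(self):
        # 30 nt + 30 nt exons with a 50 nt intron; window at protein 8..16
        tx = TranscriptModel("T", "G", "c", "+", ((100, 130), (180, 210)), 100, 210)
        pos = window_genomic_positions(tx, 8, 9)
        assert len(pos) == 27
        runs = []
        run = [pos[0]]
        for p in pos[1:]:
            if p == run[-1] + 1:
                run.append(p)
            else:
                runs.append(run)
                run = [p]
        runs.append(run)
        assert len(runs) == 2
        assert sum(len(r) for r in runs) == 27
        assert runs[0][-1] == 129 and runs[1][0] == 180

    def test_minus_strand_descends_genomically(self):
        tx = single_exon_tx(strand="-")
        pos = window_genomic_positions(tx, 1, 9)
        assert pos == list(range(159, 132, -1))
        assert sorted(pos, reverse=True) == pos

    def test_minus_strand_reverse_complement_oracle(self):
        """Bases collected along minus-strand positions spell the revcomp of the
        plus-strand slice, so transcript-order codons read correctly."""
        tx = single_exon_tx(strand="-", n_codons=9, start=0)
        genome_plus = "ACGTTGCAGATCCGGATATTCCGGAACTG"[:27]
        pos = window_genomic_positions(tx, 1, 9)
        transcript_seq = "".join(
            genome_plus[p].translate(str.maketrans("ACGT", "TGCA")) for p in pos
        )
        assert transcript_seq == reverse_complement(genome_plus)

    def test_window_past_cds_rejected(self):
        with pytest.raises(ValidationError):
            window_genomic_positions(single_exon_tx(n_codons=10), 3, 9)


def make_variant(pos1, mut="T", sample="S", chrom="c"):
    return MissenseVariant(
        sample=sample,
        chrom=chrom,
        pos=pos1,
        ref_allele="A",
        mut_allele=mut,
        gene="G",
        mrna_accession="T",
        aa_ref="K",
        aa_pos=1,
        aa_mut="M",
    )


class TestReadSupportsMutant:
    def test_alt_base_supports(self):
        read = AlignedRead("r", "c", 100, ((100, 110, 0),), "AAAAT" + "A" * 5)
        assert read_supports_mutant(read, make_variant(105, mut="T"))

    def test_reference_base_does_not(self):
        read = simple_read(100, 10)
        assert not read_supports_mutant(read, make_variant(105, mut="T"))

    def test_deletion_over_site_does_not(self):
        # two blocks abutting a 2-base deletion covering the site
        read = AlignedRead("r", "c", 100, ((100, 104, 0), (106, 112, 4)), "T" * 10)
        assert not read_supports_mutant(read, make_variant(105, mut="T"))

    def test_low_quality_base_ignored(self):
        read = AlignedRead(
            "r", "c", 100, ((100, 105, 0),), "AAAAT", base_qualities=(40, 40, 40, 40, 5)
        )
        assert not read_supports_mutant(read, make_variant(105, mut="T"))
        assert read_supports_mutant(read, make_variant(105, mut="T"), min_base_quality=0)


class TestReadSpansWindow:
    def test_full_coverage(self):
        assert read_spans_window(simple_read(100, 50), list(range(110, 137)))

    def test_26_of_27_fails(self):
        window = list(range(100, 127))
        read = simple_read(101, 50)  # misses position 100
        assert not read_spans_window(read, window)
        assert read_spans_window(read, window[1:])

    def test_spliced_read_spans_split_window(self):
        window = list(range(110, 130)) + list(range(180, 187))
        read = AlignedRead("r", "c", 100, ((100, 130, 0), (180, 200, 30)), "A" * 50)
        assert read_spans_window(read, window)

    def test_deletion_inside_window_breaks_spanning(self):
        window = list(range(100, 127))
        read = AlignedRead("r", "c", 95, ((95, 110, 0), (112, 140, 15)), "A" * 43)
        assert not read_spans_window(read, window)

    @given(st.integers(min_value=90, max_value=140), st.integers(min_value=20, max_value=60))
    def test_matches_per_position_check(self, start, length):
        window = list(range(100, 127))
        read = simple_read(start, length)
        expected = all(start <= p < start + length for p in window)
        assert read_spans_window(read, window) is expected


def _candidate(sample="S", offset=0, source="missense", peptide="ACDEFGHIK"):
    return CandidateEpitope(
        sample=sample,
        peptide=peptide,
        wt_peptide="KCDEFGHIK" if source == "missense" else "",
        allele="HLA-A*02:01",
        ic50_nM=100.0,
        source=source,
        source_key="G:p.K1M" if source == "missense" else "F5-F3",
        window_offset=offset,
    )


class TestCallExpression:
    def _setup(self, aa_pos=1):
        tx = single_exon_tx(n_codons=20)
        v = MissenseVariant(
            sample="S",
            chrom="c",
            pos=101,  # first base of codon 1, 1-based
            ref_allele="A",
            mut_allele="T",
            gene="G",
            mrna_accession="T",
            aa_ref="K",
            aa_pos=aa_pos,
            aa_mut="M",
        )
        return tx, v

    def test_one_spanning_mutant_read_is_expressed(self):
        tx, v = self._setup()
        read = AlignedRead("r", "c", 100, ((100, 130, 0),), "T" * 30)
        call = call_expression(_candidate(), v, tx, [read])
        assert call.expressed and (call.mutant_read_count, call.spanning_mutant_read_count) == (1, 1)

    def test_mutant_reads_without_full_span_are_not_expressed(self):
        tx, v = self._setup()
        reads = [
            AlignedRead(f"r{i}", "c", 95, ((95, 115, 0),), "T" * 20) for i in range(3)
        ]
        call = call_expression(_candidate(), v, tx, reads)
        assert not call.expressed
        assert (call.mutant_read_count, call.spanning_mutant_read_count) == (3, 0)

    def test_no_reads(self):
        tx, v = self._setup()
        call = call_expression(_candidate(), v, tx, [])
        assert (call.mutant_read_count, call.spanning_mutant_read_count, call.expressed) == (
            0,
            0,
            False,
        )

    def test_wildtype_spanning_read_counts_only_when_relaxed(self):
        tx, v = self._setup()
        wt_read = AlignedRead("r", "c", 100, ((100, 130, 0),), "A" * 30)
        strict = call_expression(_candidate(), v, tx, [wt_read])
        relaxed = call_expression(_candidate(), v, tx, [wt_read], strict_mutant_spanning=False)
        assert not strict.expressed
        assert relaxed.expressed and relaxed.spanning_mutant_read_count == 0

    def test_adding_reads_never_unexpresses(self):
        tx, v = self._setup()
        spanning = AlignedRead("r", "c", 100, ((100, 130, 0),), "T" * 30)
        extra = [simple_read(100, 10, read_id=f"e{i}") for i in range(5)]
        base = call_expression(_candidate(), v, tx, [spanning])
        more = call_expression(_candidate(), v, tx, [spanning, *extra])
        assert base.expressed and more.expressed


class TestFusionWindowExpression:
    def test_full_span_on_contig(self):
        c = _candidate(source="fusion")
        read = AlignedRead("r", "ctg", 0, ((0, 30, 0),), "A" * 30)
        assert fusion_window_expression(c, "ctg", [read]).expressed

    def test_five_prime_only_coverage_fails(self):
        c = _candidate(source="fusion", offset=2)  # window bases 6..33
        read = AlignedRead("r", "ctg", 0, ((0, 20, 0),), "A" * 20)
        assert not fusion_window_expression(c, "ctg", [read]).expressed

    def test_tiled_reads_match_brute_force_sweep(self):
        contig_len = 90
        reads = [
            AlignedRead(f"r{s}", "ctg", s, ((s, min(s + 30, contig_len), 0),), "A" * (min(s + 30, contig_len) - s))
            for s in range(0, contig_len - 5, 5)
        ]
        for offset in range(0, (contig_len // 3) - 9 + 1):
            window = list(range(3 * offset, 3 * offset + 27))
            brute = any(all(r.covers(p) for p in window) for r in reads)
            got = fusion_window_expression(_candidate(source="fusion", offset=offset), "ctg", reads)
            assert got.expressed is brute
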