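import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtrcall.features import (
    AlignmentSegment,
    InteinSpan,
    TRNASet,
    codon_trna_coverage,
    fiber_length_range,
    find_slippery_sites,
    gc_content,
    genome_identity,
    pairwise_identity,
    segments_from_blast6,
    splice_intein,
    tape_measure_tail_length,
)
from dtrcall.genome import GenomeInterval
from dtrcall.io import read_blast6, write_fasta
from dtrcall.simulate import build_genome


class TestInteinSplicing:
    @pytest.mark.parametrize(
        "precursor,span,expected",
        [
            (909, (131, 471), (341, 568)),   # TerL intein
            (936, (278, 584), (307, 629)),   # RNR alpha-subunit intein
            (100, (50, 50), (1, 99)),        # single-residue span
        ],
    )
    def test_worked_examples(self, precursor, span, expected):
        assert splice_intein(precursor, span) == expected

    def test_mature_sequence_concatenates_exteins(self):
        intein, mature, seq = splice_intein(10, (3, 7), "ABCDEFGHIJ")
        assert (intein, mature) == (5, 5)
        assert seq == "ABHIJ"

    def test_terminal_spans_rejected(self):
        with pytest.raises(ValueError):
            splice_intein(100, (1, 50))      # touches residue 1
        with pytest.raises(ValueError):
            splice_intein(100, (50, 100))    # touches the terminus
        with pytest.raises(ValueError):
            InteinSpan(30, 20)

    @given(
        precursor=st.integers(10, 5_000),
        start=st.integers(2, 4_000),
        length=st.integers(1, 2_000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_residue_conservation(self, precursor, start, length):
        """Intein + mature lengths always sum to the precursor length."""
        end = start + length - 1
        if end >= precursor:
            return
        intein, mature = splice_intein(precursor, (start, end))
        assert intein + mature == precursor


class TestTailCalculators:
    @pytest.mark.parametrize("aa,nm", [(1_964, 295), (2_155, 323)])
    def test_tape_measure_predictions(self, aa, nm):
        assert tape_measure_tail_length(aa) == nm

    def test_linearity_in_rise(self):
        assert tape_measure_tail_length(1_000, rise_per_residue=0.3) == 300

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tape_measure_tail_length(0)

    @pytest.mark.parametrize(
        "aa,expected",
        [(1_412, (71, 118)), (1_158, (58, 97)), (541, (28, 46)), (20, (1, 2))],
    )
    def test_fiber_ranges(self, aa, expected):
        assert fiber_length_range(aa) == expected


class TestSlipperySites:
    def test_default_motif_found(self):
        assert find_slippery_sites("GGAAAAAACTT") == [2]

    def test_colossus_heptamer_via_generic_scan(self):
        assert find_slippery_sites("TTGGGAAACTT", motifs=None) == [2]

    def test_explicit_colossus_motif(self):
        assert find_slippery_sites("TTGGGAAACTT", motifs=["GGGAAAC"]) == [2]

    def test_absent_motif_yields_empty(self):
        assert find_slippery_sites("ACGTACGTACGT") == []

    def test_non_heptamer_motif_rejected(self):
        with pytest.raises(ValueError):
            find_slippery_sites("ACGT", motifs=["AAACCC"])
        with pytest.raises(ValueError):
            find_slippery_sites("ACGT", motifs=["AACAAAC"])

    def test_region_restriction(self):
        seq = "AAAAAAC" + "G" * 20 + "AAAAAAC"
        assert find_slippery_sites(seq) == [0, 27]
        assert find_slippery_sites(seq, region=GenomeInterval(10, 34)) == [27]


class TestCodonTrnaCoverage:
    def test_no_trnas(self):
        assert codon_trna_coverage(["ATGGCTGCTTAA"], []) == (0, 0.0)

    def test_full_coverage(self):
        # codons: ATG, GCT; anticodons CAT and AGC decode them exactly
        n, frac = codon_trna_coverage(["ATGGCTGCTTAA"], ["CAT", "AGC"])
        assert (n, frac) == (2, 1.0)

    def test_partial_coverage_weighted_by_instances(self):
        # GCT appears twice, ATG once: covering only GCT gives 2/3
        n, frac = codon_trna_coverage(["ATGGCTGCT"], ["AGC"])
        assert n == 1
        assert frac == pytest.approx(2 / 3)

    def test_duplicate_anticodons_collapse(self):
        n, _ = codon_trna_coverage(["ATGGCTGCT"], ["AGC", "AGC", "agc"])
        assert n == 1

    def test_stop_codons_excluded(self):
        n, frac = codon_trna_coverage(["TAATAGTGAATG"], ["CAT"])
        assert frac == 1.0  # only ATG counts

    def test_order_invariance(self):
        cds = ["ATGGCTAAA", "GCTGCTTGG"]
        a = codon_trna_coverage(cds, ["AGC", "CAT"])
        b = codon_trna_coverage(cds[::-1], ["AGC", "CAT"])
        assert a == b

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_trna_coverage(["ATGXYZ"], ["CAT"])
        with pytest.raises(ValueError):
            codon_trna_coverage(["ATGA"], ["CAT"])

    def test_uracil_anticodons_accepted(self):
        assert TRNASet(["UUU"]).decoded_codons == {"AAA"}


def _segment(qs, qe, ss, se, pident, length=None):
    return AlignmentSegment(
        GenomeInterval(qs, qe, "+"),
        GenomeInterval(ss, se, "+"),
        pident,
        length if length is not None else se - ss,
    )


class TestGenomeIdentity:
    def test_full_length_self_match_is_100(self):
        seg = _segment(0, 40_000, 0, 40_000, 100.0)
        assert genome_identity([seg], 40_000) == 100.0

    def test_two_segment_hand_example(self):
        """10 kb @90% + 10 kb @70% on a 40 kb genome -> 80 * 0.5 = 40."""
        segs = [
            _segment(0, 10_000, 0, 10_000, 90.0),
            _segment(20_000, 30_000, 20_000, 30_000, 70.0),
        ]
        assert genome_identity(segs, 40_000) == pytest.approx(40.0)

    def test_empty_segment_list_is_zero(self):
        assert genome_identity([], 40_000) == 0.0

    def test_overlapping_segments_not_double_counted(self):
        segs = [
            _segment(0, 10_000, 0, 10_000, 100.0),
            _segment(0, 8_000, 2_000, 10_000, 100.0),
        ]
        assert genome_identity(segs, 20_000) == pytest.approx(50.0)

    def test_bounded_in_0_100(self):
        segs = [_segment(0, 5_000, 0, 5_000, 83.0)]
        value = genome_identity(segs, 5_000)
        assert 0.0 <= value <= 100.0

    def test_repeat_exclusion_drops_overlapping_segments(self):
        segs = [
            _segment(0, 10_000, 0, 10_000, 100.0),
            _segment(15_000, 20_000, 15_000, 20_000, 100.0),
        ]
        full = genome_identity(segs, 20_000)
        trimmed = genome_identity(
            segs, 20_000, exclude_interval=GenomeInterval(0, 10_000)
        )
        assert full == pytest.approx(75.0)
        assert trimmed == pytest.approx(25.0)

    def test_pairwise_reports_both_directions(self):
        segs = [_segment(0, 10_000, 0, 10_000, 90.0)]
        out = pairwise_identity(segs, 10_000, 20_000)
        assert out["query_direction"] == pytest.approx(90.0)
        assert out["subject_direction"] == pytest.approx(45.0)
        assert out["asymmetric"] is True

    def test_blast6_reversed_subject_coordinates_normalized(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q\ts\t95.5\t1000\t40\t2\t1\t1000\t2000\t1001\t1e-50\t800\n")
        (seg,) = segments_from_blast6(read_blast6(str(path)))
        assert (seg.subject_interval.start, seg.subject_interval.end) == (1_000, 2_000)
        assert seg.subject_interval.strand == "-"
        assert seg.percent_identity == 95.5


class TestBlastnIntegration:
    """Cross-check the identity statistic against real blastn alignments."""

    def _blastn(self, tmp_path, query, subject):
        qpath, spath = tmp_path / "q.fasta", tmp_path / "s.fasta"
        write_fasta(str(qpath), [("query", query)])
        write_fasta(str(spath), [("subject", subject)])
        out = tmp_path / "hits.tsv"
        subprocess.run(
            ["blastn", "-query", str(qpath), "-subject", str(spath),
             "-outfmt", "6", "-out", str(out)],
            check=True, capture_output=True,
        )
        if out.stat().st_size == 0:
            return []
        return segments_from_blast6(read_blast6(str(out)))

    def test_self_alignment_near_100(self, tmp_path):
        genome = build_genome(50_000, 5_000, 0.5, seed=120).sequence
        segs = self._blastn(tmp_path, genome, genome)
        value = genome_identity(segs, len(genome))
        assert value > 95.0

    def test_unrelated_random_genomes_below_5(self, tmp_path):
        a = build_genome(100_000, 5_000, 0.5, seed=121).sequence
        b = build_genome(100_000, 5_000, 0.5, seed=122).sequence
        segs = self._blastn(tmp_path, a, b)
        assert genome_identity(segs, len(b)) < 5.0


class TestGC:
    def test_known_values(self):
        assert gc_content("GGCC") == 100.0
        assert gc_content("ATAT") == 0.0
        assert gc_content("GCAT") == 50.0

    def test_simulated_genome_matches_request(self):
        g = build_genome(205_423, 10_287, 0.662, seed=1)
        assert round(gc_content(g.sequence), 1) == pytest.approx(66.2, abs=0.3)
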