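import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtrcall.coverage import call_terminal_repeat, detect_breakpoints, map_reads
from dtrcall.genome import Packaging, reverse_complement
from dtrcall.mapping import SeedExtendMapper
from dtrcall.simulate import DEFAULT_TAG, build_genome, ligate_tags, package_molecules
from dtrcall.tags import (
    JunctionHit,
    call_hotspots,
    find_tag_reads,
    map_junctions,
    reconcile_termini,
)

TAG = DEFAULT_TAG


def _read(rid, seq):
    return (rid, seq, "?" * len(seq))


class TestFindTagReads:
    def test_tag_plus_genomic_found(self, small_genome):
        seq = TAG + small_genome.sequence[100:400]
        (m,) = find_tag_reads([_read("a", seq)], TAG)
        assert (m.tag_start, m.tag_end, m.orientation) == (0, 49, "+")

    def test_reverse_complement_orientation(self, small_genome):
        seq = reverse_complement(TAG + small_genome.sequence[100:400])
        (m,) = find_tag_reads([_read("a", seq)], TAG)
        assert m.orientation == "-"

    def test_read_without_tag_ignored(self, small_genome):
        assert find_tag_reads([_read("a", small_genome.sequence[:300])], TAG) == []

    def test_partial_tag_rejected(self, small_genome):
        seq = TAG[10:] + small_genome.sequence[100:400]
        assert find_tag_reads([_read("a", seq)], TAG) == []

    def test_mismatch_budget(self, small_genome):
        mutated = "C" + TAG[1:] if TAG[0] != "C" else "A" + TAG[1:]
        seq = mutated + small_genome.sequence[100:400]
        assert find_tag_reads([_read("a", seq)], TAG, max_mismatch=0) == []
        (m,) = find_tag_reads([_read("a", seq)], TAG, max_mismatch=1)
        assert m.mismatches == 1

    def test_invalid_tag_rejected(self):
        with pytest.raises(ValueError):
            find_tag_reads([], "ACGTNACGTNACGTNACGTN")
        with pytest.raises(ValueError):
            find_tag_reads([], "ACGT")

    @given(
        data=st.lists(
            st.tuples(st.text("ACGT", min_size=60, max_size=200), st.booleans()),
            min_size=1, max_size=15,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_substring_scan(self, data):
        """Exact-mode detection equals a naive substring scan over all reads."""
        reads = []
        expected = set()
        rc = reverse_complement(TAG)
        for i, (seq, plant) in enumerate(data):
            if plant:
                seq = seq[:30] + TAG + seq[30:]
            reads.append(_read(f"r{i}", seq))
            if TAG in seq or rc in seq:
                expected.add(f"r{i}")
        got = {m.read_id for m in find_tag_reads(reads, TAG)}
        assert got == expected


@pytest.fixture(scope="module")
def setup():
    genome = build_genome(3_000, 300, 0.6, seed=70)
    return genome, SeedExtendMapper(genome)


class TestMapJunctions:

    def test_flank_right_of_tag(self, setup):
        genome, mapper = setup
        p = 500
        reads = find_tag_reads([_read("a", TAG + genome.sequence[p:p + 60])], TAG)
        (hit,) = map_junctions(reads, genome, mapper=mapper)
        assert (hit.junction_pos, hit.genomic_side) == (p, "right-of-tag")

    def test_flank_left_of_tag(self, setup):
        genome, mapper = setup
        p = 500
        reads = find_tag_reads([_read("a", genome.sequence[p - 60:p] + TAG)], TAG)
        (hit,) = map_junctions(reads, genome, mapper=mapper)
        assert (hit.junction_pos, hit.genomic_side) == (p - 1, "left-of-tag")

    def test_reverse_complement_read_same_junction(self, setup):
        genome, mapper = setup
        p = 500
        seq = reverse_complement(TAG + genome.sequence[p:p + 60])
        reads = find_tag_reads([_read("a", seq)], TAG)
        (hit,) = map_junctions(reads, genome, mapper=mapper)
        assert hit.junction_pos == p

    def test_flank_spanning_assembly_origin(self, setup):
        genome, mapper = setup
        L = genome.unit_length
        p = L - 30
        flank = genome.sequence[p:] + genome.sequence[:40]
        reads = find_tag_reads([_read("a", TAG + flank)], TAG)
        (hit,) = map_junctions(reads, genome, mapper=mapper)
        assert hit.junction_pos == p

    def test_short_flank_skipped(self, setup):
        genome, mapper = setup
        reads = find_tag_reads([_read("a", TAG + genome.sequence[500:510])], TAG)
        assert map_junctions(reads, genome, mapper=mapper) == []


def _junctions(positions):
    return [
        JunctionHit(f"r{i}", int(p), "right-of-tag", "+", 0)
        for i, p in enumerate(positions)
    ]


class TestHotspots:
    def test_two_loci_stand_out_of_uniform_background(self):
        """15 junction reads at two termini + 26 random breaks: exactly the
        two termini are called."""
        L = 205_423
        rng = np.random.default_rng(80)
        positions = [68_474] * 8 + [78_760] * 7 + list(rng.integers(0, L, size=26))
        calls = call_hotspots(_junctions(positions), L)
        assert sorted(c.position for c in calls) == [68_474, 78_760]
        assert all(c.p_value < 0.05 for c in calls)
        assert {c.support for c in calls} == {7, 8}

    def test_uniform_junctions_rarely_call(self):
        L = 205_423
        rng = np.random.default_rng(81)
        hits = sum(
            bool(call_hotspots(_junctions(rng.integers(0, L, size=41)), L))
            for _ in range(300)
        )
        assert hits / 300 <= 0.10

    def test_single_junction_never_a_hotspot(self):
        assert call_hotspots(_junctions([100]), 10_000) == []

    def test_no_junctions_rejected(self):
        with pytest.raises(ValueError):
            call_hotspots([], 10_000)

    def test_wraparound_cluster_merged(self):
        L = 10_000
        calls = call_hotspots(_junctions([L - 1, 0, L - 2]), L, alpha=0.05)
        assert len(calls) == 1
        assert calls[0].support == 3


@pytest.fixture(scope="module")
def repeat_call():
    g = build_genome(20_000, 2_000, 0.66, seed=90)
    mols = package_molecules(g, 30, Packaging.NONPERMUTED_REPEAT, seed=91)
    from dtrcall.simulate import shotgun_reads

    reads = shotgun_reads(mols, fold_coverage=100, seed=92, unit_length=20_000)
    profile = map_reads(reads, g)
    return g, call_terminal_repeat(detect_breakpoints(profile), profile)


class TestReconcile:

    def test_exact_hotspots_confirm(self, repeat_call):
        g, call = repeat_call
        L = g.unit_length
        from dtrcall.tags import HotspotCall

        hs = [
            HotspotCall(call.left.position, 8, 0.001, 1e-20),
            HotspotCall((call.right.position - 1) % L, 7, 0.001, 1e-20),
        ]
        report = reconcile_termini(call, hs, L)
        assert report.verdict == "confirmed"
        assert (report.left_distance, report.right_distance) == (0, 0)

    def test_one_matching_boundary_is_partial(self, repeat_call):
        g, call = repeat_call
        from dtrcall.tags import HotspotCall

        hs = [HotspotCall((call.left.position + 3) % g.unit_length, 5, 0.001, 1e-10)]
        report = reconcile_termini(call, hs, g.unit_length)
        assert report.verdict == "partial"
        assert report.left_distance == 3

    def test_no_hotspots_is_coverage_only(self, repeat_call):
        g, call = repeat_call
        assert reconcile_termini(call, [], g.unit_length).verdict == "coverage-only"

    def test_no_repeat_call_is_tag_only(self):
        from dtrcall.tags import HotspotCall

        report = reconcile_termini(None, [HotspotCall(5, 4, 0.1, 0.001)], 10_000)
        assert report.verdict == "tag-only"

    def test_far_hotspots_are_discordant(self, repeat_call):
        g, call = repeat_call
        from dtrcall.tags import HotspotCall

        mid = (call.left.position + 1_000) % g.unit_length
        report = reconcile_termini(call, [HotspotCall(mid, 5, 0.1, 0.001)], g.unit_length)
        assert report.verdict == "discordant"


class TestEndToEndTagConfirmation:
    def test_termini_fraction_one_reconciles_at_zero_distance(self, small_genome, small_simulation):
        """With every tag event at a true terminus, hotspots fall exactly on
        both repeat boundaries."""
        molecules, reads = small_simulation
        L = small_genome.unit_length
        mapper = SeedExtendMapper(small_genome)
        profile = map_reads(reads, small_genome, mapper=mapper)
        call = call_terminal_repeat(detect_breakpoints(profile), profile)
        tagged = ligate_tags(
            molecules, termini_fraction=1.0, n_tagged=30, seed=95, unit_length=L
        )
        matches = find_tag_reads(tagged, TAG)
        assert len(matches) == 30
        junctions = map_junctions(matches, small_genome, mapper=mapper)
        truth = {r.id: r.truth.junction for r in tagged}
        assert all(j.junction_pos == truth[j.read_id] for j in junctions)
        hotspots = call_hotspots(junctions, L)
        report = reconcile_termini(call, hotspots, L)
        assert report.verdict == "confirmed"
        assert report.left_distance == 0 and report.right_distance == 0
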