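"""Tandem-array decomposition, unit typing, motif scanners, hairpins,
and control-region partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocr.control_region import (
    PartitionConfig,
    adjacency_patterns,
    classify_units,
    content_blocks,
    detect_tandem_array,
    find_hairpin,
    find_homopolymers,
    find_microsatellites,
    partition_control_region,
    write_bed,
)
from mitocr.core import SequenceError, reverse_complement
from mitocr.synthetic import expected_partition_kinds


def _gc_flank(rng, n):
    """Flank that cannot extend an A/T-containing repeat unit."""
    return "".join(rng.choice(list("GC"), size=n))


class TestDetectTandemArray:
    def test_planted_dinucleotide_array_in_flanks(self):
        # fixed repeat-free flanks that cannot extend the A/T unit
        seq = "GGCCGCGGCA" + "AT" * 5 + "GCCGGCACGG"
        arrays = detect_tandem_array(seq, min_period=2, min_copies=4)
        assert len(arrays) == 1
        assert arrays[0].period == 2
        assert arrays[0].n_full == 5
        assert arrays[0].consensus == "AT"

    def test_no_repeat_gives_empty_list(self):
        assert detect_tandem_array("ACGT") == []

    def test_paper_default_synthetic_array(self, default_repeat_array):
        seq, truth = default_repeat_array
        arrays = detect_tandem_array(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 18
        assert a.n_full + a.n_partial == 53
        assert a.length == 949
        assert a.length == 52 * 18 + 13

    def test_unit_length_bookkeeping(self, default_repeat_array):
        seq, _ = default_repeat_array
        a = detect_tandem_array(seq)[0]
        a.validate()
        assert sum(u[1] for u in a.units) == a.length

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_decomposer_exactness_on_random_unit_arrays(self, data):
        """A pure array of c copies of a random p-mer plus a prefix partial
        is recovered exactly: period, copy count, partial, total length."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        p = data.draw(st.integers(5, 40))
        c = data.draw(st.integers(3, 60))
        unit = "".join(rng.choice(list("ACGT"), size=p))
        # require a non-degenerate unit (a homopolymer p-mer is period 1)
        if len(set(unit)) == 1:
            unit = unit[:-1] + ("A" if unit[0] != "A" else "C")
        q = data.draw(st.integers(0, p - 1))
        seq = unit * c + unit[:q]
        arrays = detect_tandem_array(seq, min_period=2, max_period=250)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.start, a.end) == (1, len(seq))
        if a.period == p:  # p-mer itself may be internally periodic
            assert a.n_full == c
            assert a.n_partial == (1 if q else 0)
            assert a.consensus == unit
        else:
            assert a.period == min(
                d for d in range(1, p + 1) if p % d == 0 and unit == unit[:d] * (p // d)
            )

    def test_smaller_period_preferred_over_multiple(self):
        seq = "GATTAC" * 12
        arrays = detect_tandem_array(seq, min_period=2)
        assert arrays[0].period == 6


class TestClassifyUnits:
    def test_homogeneous_array(self):
        a = detect_tandem_array("ACGTTACCA" * 6, min_period=2)[0]
        asg = classify_units(a)
        assert asg.variable_sites == []
        assert asg.counts == {1: 6}

    def test_paper_default_types_recovered(self, default_repeat_array):
        seq, truth = default_repeat_array
        a = detect_tandem_array(seq)[0]
        asg = classify_units(a)
        assert asg.variable_sites == list(truth.variable_sites)
        assert sorted(asg.counts.values(), reverse=True) == [18, 15, 15, 4]
        assert asg.labels == truth.unit_labels
        assert asg.partial_label == 1
        assert sum(asg.counts.values()) == a.n_full

    def test_three_variants_at_one_site(self):
        base = "ACGTTACCAGGA"
        units = []
        for res, n in (("T", 4), ("G", 3), ("C", 2)):
            units += [base[:6] + res + base[7:]] * n
        rng = np.random.default_rng(2)
        order = rng.permutation(len(units))
        seq = "".join(units[i] for i in order)
        a = detect_tandem_array(seq, min_period=2)[0]
        asg = classify_units(a)
        assert asg.variable_sites == [6]
        assert sorted(asg.counts.values(), reverse=True) == [4, 3, 2]

    def test_singleton_combo_merged_into_nearest_type(self):
        base = "ACGTTACCAGGA"
        units = [base] * 5 + [base[:6] + "T" + base[7:]] * 3
        units.append(base[:2] + "A" + base[3:])  # point mutation of the majority
        seq = "".join(units)
        a = detect_tandem_array(seq, min_period=2)[0]
        asg = classify_units(a, min_minor_count=2)
        assert sorted(asg.counts.values(), reverse=True) == [6, 3]

    def test_too_few_units_is_an_error(self):
        a = detect_tandem_array("ACGTTACCA" * 6, min_period=2)[0]
        a.units = a.units[:1]
        a.n_full = 1
        with pytest.raises(SequenceError):
            classify_units(a)


class TestAdjacency:
    def _assignment(self, labels, partial=None):
        from mitocr.control_region import UnitTypeAssignment

        adj = {}
        for x, y in zip(labels, labels[1:]):
            adj.setdefault(x, {}).setdefault(y, 0)
            adj[x][y] += 1
        return UnitTypeAssignment(
            variable_sites=[], labels=labels, type_definitions={},
            counts={}, adjacency=adj, partial_label=partial,
        )

    def test_transition_counts_by_hand(self):
        rep = adjacency_patterns(self._assignment([1, 2, 3, 1, 2, 3]))
        assert rep.transitions == {1: {2: 2}, 2: {3: 2}, 3: {1: 1}}
        assert rep.always_followed_by(1, 2)

    def test_rule_holds(self):
        assert adjacency_patterns(self._assignment([4, 2, 4, 2])).always_followed_by(4, 2)

    def test_rule_fails(self):
        assert not adjacency_patterns(self._assignment([4, 3])).always_followed_by(4, 2)

    def test_terminal_occurrence_breaks_rule(self):
        assert not adjacency_patterns(self._assignment([2, 4])).always_followed_by(4, 2)

    def test_single_unit_is_an_error(self):
        with pytest.raises(SequenceError):
            adjacency_patterns(self._assignment([1]))


class TestHomopolymers:
    def test_eight_bp_poly_c(self):
        hits = find_homopolymers("ATG" + "C" * 8 + "GTA", min_len=8)
        assert [(h.motif, h.length) for h in hits] == [("C", 8)]

    def test_alternation_is_not_a_homopolymer(self):
        assert find_homopolymers("ACACACACAC", min_len=3) == []

    def test_case_normalization(self):
        hits = find_homopolymers("AAAAaaAA", min_len=8)
        assert len(hits) == 1 and hits[0].length == 8

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            find_homopolymers("AAA", min_len=2)


class TestMicrosatellites:
    def test_aattt_times_three(self):
        hits = find_microsatellites("AATTTAATTTAATTT")
        assert [(h.motif, h.copies) for h in hits] == [("AATTT", 3)]

    def test_ta_times_five(self):
        hits = find_microsatellites("TATATATATA")
        assert [(h.motif, h.copies) for h in hits] == [("TA", 5)]

    def test_homopolymer_not_reported_at_period_two(self):
        assert find_microsatellites("AAAA", min_copies=2) == []

    def test_reducible_motif_reported_at_shortest_period(self):
        hits = find_microsatellites("GCGCGCGCGCGC")
        assert len(hits) == 1 and hits[0].motif == "GC"


class TestContentBlocks:
    def test_all_a_sequence_single_block(self):
        hits = content_blocks("A" * 50, window=20, threshold=0.9, mode="AT")
        assert [(h.start, h.end) for h in hits] == [(1, 50)]
        assert hits[0].content == 1.0

    def test_alternating_sequence_below_threshold(self):
        assert content_blocks("ACGT" * 20, window=20, threshold=0.9, mode="AT") == []

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            content_blocks("ACGT", window=20, threshold=0.9, mode="AT")

    def test_block_content_recomputed_on_merged_slice(self):
        seq = "A" * 30 + "G" * 30
        (hit,) = content_blocks(seq, window=10, threshold=0.9, mode="AT")
        assert hit.end - hit.start + 1 >= 30
        assert hit.content == pytest.approx(
            sum(1 for b in seq[hit.start - 1 : hit.end] if b in "AT") / hit.length
        )


def _oracle_has_hairpin(seq, min_stem, max_loop, min_loop=3):
    """Exhaustive perfect-inverted-repeat scan (mismatch-free)."""
    n = len(seq)
    for i in range(n):
        for a in range(min_stem, (n - i) // 2 + 1):
            for loop in range(min_loop, max_loop + 1):
                j = i + a + loop
                if j + a > n:
                    break
                if seq[i : i + a] == reverse_complement(seq[j : j + a]):
                    return True
    return False


class TestHairpin:
    def test_constructed_perfect_inverted_repeat(self):
        seq = "TATA" + "GGGGGG" + "AAAA" + "CCCCCC"
        hits = find_hairpin(seq, min_stem=6, max_loop=6, max_mismatch=0)
        assert hits
        h = max(hits, key=lambda h: h.extras["stem_len"])
        assert h.extras["stem_len"] == 6
        assert h.extras["loop_len"] == 4
        assert h.extras["tata_upstream"]

    def test_agrees_with_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            found = bool(find_hairpin(seq, min_stem=6, max_loop=8, max_mismatch=0))
            assert found == _oracle_has_hairpin(seq, min_stem=6, max_loop=8)

    def test_homopolymer_has_no_hairpin(self):
        assert find_hairpin("A" * 40, min_stem=6, max_loop=8, max_mismatch=0) == []

    def test_min_stem_floor(self):
        with pytest.raises(ValueError):
            find_hairpin("ACGT", min_stem=3)


class TestPartition:
    def test_synthetic_control_region_order(self, default_control_region):
        seq, truth = default_control_region
        part = partition_control_region(seq)
        assert part.kinds == expected_partition_kinds(truth)

    def test_at_block_length_and_content(self, default_control_region):
        seq, truth = default_control_region
        part = partition_control_region(seq)
        at = next(s for s in part.segments if s.kind == "at_block")
        assert at.length == 103
        content = sum(1 for b in seq[at.start - 1 : at.end] if b in "AT") / at.length
        assert content == pytest.approx(0.903, abs=0.005)

    def test_segments_tile_the_input(self, default_control_region):
        seq, _ = default_control_region
        part = partition_control_region(seq)
        part.validate(len(seq))
        assert part.segments[0].start == 1 and part.segments[-1].end == len(seq)

    def test_motif_free_sequence_is_unassigned(self):
        # frozen random 60-mer verified to carry no scanner feature
        seq = "TCAAGTAATATTAATTTTACCCATATTTTGTATATATTAGTGAAATATAGTGTTTAAATT"
        part = partition_control_region(seq)
        assert part.kinds == ["unassigned"]

    def test_pure_array_is_single_segment(self, default_repeat_array):
        seq, _ = default_repeat_array
        part = partition_control_region(seq)
        assert part.kinds == ["tandem_array"]

    def test_bed_output_is_zero_based_half_open(self, tmp_path, default_repeat_array):
        seq, _ = default_repeat_array
        part = partition_control_region(seq)
        bed = tmp_path / "part.bed"
        write_bed(part, bed, chrom="cr")
        line = bed.read_text().splitlines()[0].split("\t")
        assert line == ["cr", "0", "949", "tandem_array"]
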