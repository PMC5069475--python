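"""Generators: determinism, planted structure, round trips with the
analysis modules."""

import dataclasses
import math

import numpy as np
import pytest

from mitocr.composition import base_composition, skew
from mitocr.control_region import detect_tandem_array, partition_control_region
from mitocr.synthetic import (
    CompositionParams,
    CRGeneratorConfig,
    UnsatisfiableArrangement,
    expected_partition_kinds,
    generate_cds_pair,
    generate_control_region,
    generate_family_alignment,
    generate_mitogenome,
    generate_repeat_array,
)


class TestRepeatArrayGenerator:
    def test_default_length_949(self, default_repeat_array):
        seq, truth = default_repeat_array
        assert len(seq) == 949 == 52 * 18 + 13

    def test_deterministic_per_seed(self):
        assert generate_repeat_array(seed=4)[0] == generate_repeat_array(seed=4)[0]
        assert generate_repeat_array(seed=4)[0] != generate_repeat_array(seed=5)[0]

    def test_arrangement_rules_hold_in_ground_truth(self):
        for seed in range(5):
            _, truth = generate_repeat_array(seed=seed)
            labels = truth.unit_labels
            assert labels[0] == 1  # starts with Type I
            for i, lab in enumerate(labels):
                if lab == 4:
                    assert labels[i + 1] == 2
                if lab == 3:
                    assert labels[i - 1] == 2 and labels[i + 1] == 1

    def test_homogeneous_two_copy_array(self):
        cfg = CRGeneratorConfig(type_counts=(2, 0, 0, 0), partial_prefix_len=0)
        seq, truth = generate_repeat_array(cfg, seed=0)
        assert seq == CRGeneratorConfig().unit_templates[0] * 2
        assert truth.unit_labels == [1, 1]

    def test_unsatisfiable_rules_raise_naming_the_rule(self):
        cfg = CRGeneratorConfig(type_counts=(0, 0, 0, 1))
        with pytest.raises(UnsatisfiableArrangement, match="Type IV"):
            generate_repeat_array(cfg, seed=0)


class TestControlRegionGenerator:
    def test_total_length_is_sum_of_elements(self, default_control_region):
        seq, _ = default_control_region
        cfg = CRGeneratorConfig()
        expected = (
            cfg.gc_block_len
            + len(cfg.microsat_1[0]) * cfg.microsat_1[1]
            + cfg.polyc_len
            + len(cfg.microsat_2[0]) * cfg.microsat_2[1]
            + cfg.at_block_len
            + cfg.polya_len
            + cfg.pre_array_linker
            + 949
            + cfg.post_array_linker
            + 4  # TATA
            + 2 * len(cfg.hairpin_arm)
            + len(cfg.hairpin_loop)
        )
        assert len(seq) == expected

    def test_partition_round_trip_recovers_element_order(self):
        for seed in (2, 3):
            seq, truth = generate_control_region(seed=seed)
            part = partition_control_region(seq)
            assert part.kinds == expected_partition_kinds(truth)

    def test_ground_truth_segments_tile_the_sequence(self, default_control_region):
        seq, truth = default_control_region
        assert truth.segments[0][1] == 1
        assert truth.segments[-1][2] == len(seq)
        for (_, _, e1), (_, s2, _) in zip(truth.segments, truth.segments[1:]):
            assert s2 == e1 + 1

    def test_pure_at_block_option(self):
        cfg = CRGeneratorConfig(at_content=1.0)
        seq, truth = generate_control_region(cfg, seed=0)
        kind, s, e = next(seg for seg in truth.segments if seg[0] == "at_block")
        assert set(seq[s - 1 : e]) <= {"A", "T"}

    def test_deterministic_per_seed(self):
        assert generate_control_region(seed=8)[0] == generate_control_region(seed=8)[0]


class TestMitogenomeGenerator:
    def test_genome_length_matches_reference_architecture(self):
        genome, ann, _ = generate_mitogenome(seed=0)
        assert len(genome.seq) == 16345 == ann.genome_length

    def test_same_seed_identical_fasta(self, tmp_path):
        from mitocr.core import write_fasta

        g1, _, _ = generate_mitogenome(seed=2)
        g2, _, _ = generate_mitogenome(seed=2)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta([g1], p1)
        write_fasta([g2], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_skew_target_recovered_on_gene_bodies(self):
        genome, ann, _ = generate_mitogenome(
            composition_params=CompositionParams(at_content=0.76, at_skew=0.0), seed=6
        )
        bodies = "".join(
            genome.seq[r.start - 1 : r.end] for r in ann.records if r.kind != "control_region"
        )
        comp = base_composition(bodies)
        n_at = comp.n_counted * comp.at
        se = 1.0 / math.sqrt(n_at)  # binomial MC error of the skew estimate
        assert abs(skew(comp).at_skew) <= 3 * se

    def test_planted_skew_target_recovered(self):
        genome, ann, _ = generate_mitogenome(
            composition_params=CompositionParams(at_content=0.76, at_skew=0.15), seed=6
        )
        j_bodies = "".join(
            genome.seq[r.start - 1 : r.end]
            for r in ann.records
            if r.kind != "control_region" and r.strand == "J"
        )
        comp = base_composition(j_bodies)
        se = 1.0 / math.sqrt(comp.n_counted * comp.at)
        assert abs(skew(comp).at_skew - 0.15) <= 4 * se  # start/stop planting adds tiny bias

    def test_embedded_control_region_architecture(self):
        genome, ann, truth = generate_mitogenome(seed=1)
        control = ann.get("control_region")
        cr_seq = genome.seq[control.start - 1 : control.end]
        arrays = detect_tandem_array(cr_seq, min_period=7)
        assert len(arrays) == 1
        assert arrays[0].period == 18
        assert arrays[0].n_full + arrays[0].n_partial == 53


class TestFamilyAlignmentGenerator:
    def test_full_identity(self):
        from mitocr.trna import inp_percent

        aln, _ = generate_family_alignment(6, 50, identity_prob=1.0, seed=0)
        assert inp_percent(aln).inp_percent == 100.0

    def test_intermediate_identity_within_binomial_error(self):
        from mitocr.trna import inp_percent

        aln, truth = generate_family_alignment(10, 1000, identity_prob=0.5, seed=3)
        measured = inp_percent(aln).inp_percent
        se = 100.0 * math.sqrt(0.5 * 0.5 / 1000)
        assert abs(measured - 50.0) <= 3 * se + 100 * (0.25) ** 9  # + accidental-identity slack

    def test_planted_columns_match_profile(self):
        from mitocr.trna import inp_percent

        aln, truth = generate_family_alignment(4, 200, identity_prob=0.7, seed=9)
        prof = inp_percent(aln)
        for cls, planted in zip(prof.classes, truth.extras["planted_identical"]):
            if planted:
                assert cls == "identical"


class TestCdsPairGenerator:
    def test_no_nonsynonymous_changes_means_ka_zero(self):
        from mitocr.evo_rates import ng86_kaks

        a, b, _ = generate_cds_pair(200, 0.1, 0.0, seed=0)
        assert ng86_kaks(a, b).ka == 0.0

    def test_no_synonymous_changes_flags_ratio(self):
        from mitocr.evo_rates import ng86_kaks

        a, b, _ = generate_cds_pair(200, 0.0, 0.05, seed=1)
        r = ng86_kaks(a, b)
        assert r.ks == 0.0 and r.ratio is None

    def test_no_stops_anywhere(self):
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        stops = set(unambiguous_dna_by_id[5].stop_codons)
        a, b, _ = generate_cds_pair(300, 0.1, 0.1, seed=2)
        for s in (a, b):
            assert not any(s[i : i + 3] in stops for i in range(0, len(s), 3))

    def test_truth_counts_match_observed_differences(self):
        a, b, truth = generate_cds_pair(400, 0.06, 0.03, seed=5)
        n_diff_codons = sum(a[i : i + 3] != b[i : i + 3] for i in range(0, len(a), 3))
        assert n_diff_codons == truth.extras["n_syn"] + truth.extras["n_nonsyn"]
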