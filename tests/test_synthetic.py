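"""Synthetic-genome generator: determinism, planted-truth recovery, evolution op."""

import numpy as np
import pytest

from apfam.duplication import ng86
from apfam.family import confirmed_members, identify_family
from apfam.promoter import CIS_ELEMENT_CATALOG, scan_elements
from apfam.synthetic import (
    SimulationConfig,
    evolve_codon_pair,
    make_expression,
    plant_cis_elements,
    simulate_family_genome,
)

from oracles import random_stop_free_cds, scan_oracle


class TestSimulateFamilyGenome:
    def test_same_seed_reproducible(self):
        cfg = SimulationConfig(
            seed=5, n_chromosomes=2, chromosome_length_bp=900_000,
            n_family_genes=6, category_mix=(1, 1, 4),
            tandem_cluster_sizes=(2,), segmental_pairs=((8, 1),),
            n_xylem_specific=2,
        )
        a, b = simulate_family_genome(cfg), simulate_family_genome(cfg)
        assert a.assembly.sequences == b.assembly.sequences
        assert a.cds == b.cds and a.proteins == b.proteins
        assert a.truth.promoter_hits == b.truth.promoter_hits
        assert a.expression.equals(b.expression)

    def test_planted_categories_recovered_exactly(self, small_dataset):
        members = identify_family(small_dataset.cds, small_dataset.proteins)
        confirmed = confirmed_members(members)
        assert len(confirmed) == len(small_dataset.genes)
        for m in confirmed:
            assert m.category == small_dataset.truth.categories[m.gene_id], m.gene_id

    def test_planted_tandem_cluster_recovered(self, small_dataset):
        from apfam.duplication import find_tandem

        intervals = [(g.gene_id, g.interval) for g in small_dataset.genes]
        got = [sorted(c) for c in find_tandem(intervals)]
        expected = [sorted(c) for c in small_dataset.truth.tandem_clusters]
        assert sorted(map(tuple, got)) == sorted(map(tuple, expected))

    def test_infeasible_config_errors(self):
        cfg = SimulationConfig(
            seed=0, n_chromosomes=2, chromosome_length_bp=50_000,
            n_family_genes=6, category_mix=(1, 1, 4),
            tandem_cluster_sizes=(2,), segmental_pairs=((5, 1),),
            n_xylem_specific=1,
        )
        with pytest.raises(ValueError, match="infeasible"):
            simulate_family_genome(cfg)

    def test_inconsistent_mix_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_family_genes=10, category_mix=(1, 1, 4))


class TestEvolveCodonPair:
    def test_single_synonymous_substitution_detected_by_ng86(self, rng):
        cds = "GGG" * 9
        mutated, rec = evolve_codon_pair(cds, 1, 0, rng)
        assert rec.n_syn == 1 and rec.n_nonsyn == 0
        pairs = [(cds[i : i + 3], mutated[i : i + 3]) for i in range(0, 27, 3)]
        r = ng86(pairs)
        assert (r.sd, r.nd) == (1.0, 0.0)

    def test_zero_request_is_identity(self, rng):
        cds = random_stop_free_cds(rng, 20)
        mutated, rec = evolve_codon_pair(cds, 0, 0, rng)
        assert mutated == cds and rec.n_syn == rec.n_nonsyn == 0

    def test_same_seed_same_mutations(self, rng):
        cds = random_stop_free_cds(rng, 40)
        a = evolve_codon_pair(cds, 4, 2, 123)
        b = evolve_codon_pair(cds, 4, 2, 123)
        assert a == b

    def test_realized_counts_and_protein_effect(self, rng):
        from apfam.io_model import translate

        cds = random_stop_free_cds(rng, 50) + "TAA"
        mutated, rec = evolve_codon_pair(cds, 5, 3, rng)
        assert (rec.n_syn, rec.n_nonsyn) == (5, 3)
        p0 = translate(cds).protein
        p1 = translate(mutated).protein
        diff = sum(1 for x, y in zip(p0, p1) if x != y)
        assert diff == 3  # nonsynonymous changes only

    def test_infeasible_request_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            evolve_codon_pair("ATGGGG", 10, 0, 0)


class TestPlantCisElements:
    def test_planted_instance_recovered_at_position_and_strand(self):
        seq, truth = plant_cis_elements(500, [("ACI", 100, "+")], seed=4)
        assert truth == [("ACI", 101, "+", "ACCTACC")]
        hits = {(h.element, h.start, h.strand) for h in scan_elements(seq)}
        assert ("ACI", 101, "+") in hits

    def test_minus_strand_instance_needs_both_strand_scan(self):
        seq, truth = plant_cis_elements(500, [("SNBE", 200, "-")], seed=4)
        (el, start, strand, matched) = truth[0]
        both = {(h.element, h.start, h.strand) for h in scan_elements(seq)}
        assert (el, start, strand) in both
        plus_only = {
            (h.element, h.start, h.strand)
            for h in scan_elements(seq, strands="plus")
        }
        oracle_plus = scan_oracle(seq, CIS_ELEMENT_CATALOG, strands="plus")
        assert plus_only == oracle_plus  # recovered only if background fires too

    def test_overlapping_instances_error(self):
        with pytest.raises(ValueError, match="overlap"):
            plant_cis_elements(500, [("ACI", 100, "+"), ("ACII", 103, "+")], seed=0)

    def test_no_instances_matches_background_oracle(self):
        seq, truth = plant_cis_elements(800, [], seed=9)
        assert truth == []
        got = {(h.element, h.start, h.strand) for h in scan_elements(seq)}
        assert got == scan_oracle(seq, CIS_ELEMENT_CATALOG)


class TestMakeExpression:
    def test_zero_noise_equals_archetypes(self):
        arch = {"g1": {t: 100.0 for t in "ABCDEF"}}
        df = make_expression(["g1"], arch, 0.0, seed=0, tissues=list("ABCDEF"))
        assert (df.loc["g1"] == 100.0).all()

    def test_same_seed_identical(self):
        arch = {"g1": {t: 100.0 for t in "AB"}, "g2": {t: 50.0 for t in "AB"}}
        a = make_expression(["g1", "g2"], arch, 25.0, seed=3, tissues=["A", "B"])
        b = make_expression(["g1", "g2"], arch, 25.0, seed=3, tissues=["A", "B"])
        assert a.equals(b)

    def test_values_non_negative(self):
        arch = {"g1": {t: 1.0 for t in "AB"}}
        df = make_expression(["g1"], arch, 500.0, seed=1, tissues=["A", "B"])
        assert (df >= 0).all().all()
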