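"""Tandem/segmental rules, NG86 Ka/Ks, molecular-clock dating."""

import itertools

import pytest

from apfam.duplication import (
    DuplicationBlockTable,
    assign_segmental,
    codon_align,
    date_duplication,
    find_tandem,
    ng86,
    selection_class,
)
from apfam.io_model import GenomeInterval

from oracles import ng86_oracle, random_stop_free_cds


def iv(chrom, start, end):
    return GenomeInterval(chrom, start, end)


class TestFindTandem:
    def test_within_50kb_clustered(self):
        members = [("g1", iv("c1", 100000, 102000)), ("g2", iv("c1", 130000, 133000))]
        assert find_tandem(members) == [["g1", "g2"]]

    def test_beyond_50kb_not_clustered(self):
        members = [("g1", iv("c1", 100000, 102000)), ("g2", iv("c1", 162001, 165000))]
        assert find_tandem(members) == []

    def test_single_linkage_chain(self):
        members = [
            ("g1", iv("c1", 0, 2000)),
            ("g2", iv("c1", 42000, 44000)),  # 40 kb from g1
            ("g3", iv("c1", 89000, 91000)),  # 45 kb from g2
        ]
        assert find_tandem(members) == [["g1", "g2", "g3"]]

    def test_matches_brute_force_pair_closure(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 15))
            members = []
            for i in range(n):
                chrom = f"c{int(rng.integers(1, 3))}"
                start = int(rng.integers(0, 500_000))
                members.append((f"g{i}", iv(chrom, start, start + 1000)))
            got = {frozenset(c) for c in find_tandem(members)}
            # brute force: union-find over all within-window pairs
            parent = {g: g for g, _ in members}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for (ga, iva), (gb, ivb) in itertools.combinations(members, 2):
                if iva.chrom == ivb.chrom and iva.gap_to(ivb) <= 50000:
                    parent[find(ga)] = find(gb)
            groups = {}
            for g, _ in members:
                groups.setdefault(find(g), set()).add(g)
            expected = {frozenset(s) for s in groups.values() if len(s) >= 2}
            assert got == expected


class TestAssignSegmental:
    def blocks(self):
        return DuplicationBlockTable(
            [("b1", iv("c1", 1000, 5000), iv("c2", 9000, 14000))]
        )

    def test_pair_emitted_for_both_sides(self):
        members = [("g1", iv("c1", 2000, 2500)), ("g2", iv("c2", 10000, 10500))]
        assert assign_segmental(members, self.blocks()) == [("g1", "g2", "b1")]

    def test_single_side_gives_no_pair(self):
        members = [("g1", iv("c1", 2000, 2500)), ("g2", iv("c2", 90000, 90500))]
        assert assign_segmental(members, self.blocks()) == []

    def test_one_bp_overlap_counts(self):
        members = [("g1", iv("c1", 4999, 6000)), ("g2", iv("c2", 9000, 9100))]
        assert assign_segmental(members, self.blocks()) == [("g1", "g2", "b1")]


class TestCodonAlign:
    def test_identical_sequences(self):
        ca = codon_align("ATGAAACCCGGG", "ATGAAACCCGGG", ("MKPG", "MKPG"))
        assert len(ca.pairs) == 4 and ca.n_dropped == 0

    def test_gap_column_dropped(self):
        ca = codon_align("ATGAAACCC", "ATGCCC", ("MKP", "M-P"))
        assert [p for p in ca.pairs] == [("ATG", "ATG"), ("CCC", "CCC")]

    def test_trailing_stops_stripped(self):
        ca = codon_align("ATGAAATAA", "ATGAAATGA", ("MK", "MK"))
        assert len(ca.pairs) == 2

    def test_n_containing_pairs_dropped_and_counted(self):
        ca = codon_align("ATGANA", "ATGAAA", ("MX", "MK"))
        assert len(ca.pairs) == 1 and ca.n_dropped == 1

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            codon_align("ATGAAA", "ATGAAA", ("MKV", "MKV"))


class TestNg86:
    def test_worked_toy(self):
        pairs = [("GGG", "GGG")] * 8 + [("GGG", "GGA")]
        r = ng86(pairs)
        assert r.S_sites == pytest.approx(9.0)
        assert r.N_sites == pytest.approx(18.0)
        assert (r.sd, r.nd) == (1.0, 0.0)
        assert r.ps == pytest.approx(1 / 9)
        assert r.Ks == pytest.approx(0.1203, abs=1e-4)
        assert r.Ka == 0.0

    def test_identical_sequences_zero_and_undefined_ratio(self):
        r = ng86([("ATG", "ATG"), ("GGC", "GGC")])
        assert (r.Ks, r.Ka, r.ratio) == (0.0, 0.0, None)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = random_stop_free_cds(rng, 15)
            b = random_stop_free_cds(rng, 15)
            pairs = [(a[i : i + 3], b[i : i + 3]) for i in range(0, 45, 3)]
            fwd = ng86(pairs)
            rev = ng86([(y, x) for x, y in pairs])
            assert fwd.sd == pytest.approx(rev.sd, abs=1e-12)
            assert fwd.nd == pytest.approx(rev.nd, abs=1e-12)
            assert fwd.S_sites == pytest.approx(rev.S_sites, abs=1e-12)

    def test_site_conservation(self, rng):
        for _ in range(10):
            pairs = [
                (random_stop_free_cds(rng, 1), random_stop_free_cds(rng, 1))
                for _ in range(20)
            ]
            r = ng86(pairs)
            assert r.S_sites + r.N_sites == pytest.approx(3 * len(pairs), abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            pairs = [
                (random_stop_free_cds(rng, 1), random_stop_free_cds(rng, 1))
                for _ in range(30)
            ]
            r = ng86(pairs)
            S, N, sd, nd, ps, pn, Ks, Ka = ng86_oracle(pairs)
            assert abs(r.S_sites - S) < 1e-12
            assert abs(r.sd - sd) < 1e-12
            assert abs(r.nd - nd) < 1e-12
            if Ks is None:
                assert r.saturated
            else:
                assert abs(r.Ks - Ks) < 1e-12 and abs(r.Ka - Ka) < 1e-12

    def test_stop_pairs_dropped(self):
        r = ng86([("ATG", "ATG"), ("TAA", "ATG")])
        assert r.n_codons == 1 and r.n_dropped == 1


class TestDating:
    def test_zero(self):
        assert date_duplication(0.0) == 0.0

    def test_printed_formula(self):
        # Ks = 0.182 at lambda 9.1e-9 -> exactly 10 Mya
        assert date_duplication(0.182) / 1e6 == pytest.approx(10.0)

    def test_linearity(self):
        assert date_duplication(0.4) == pytest.approx(2 * date_duplication(0.2))

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            date_duplication(-0.1)


class TestSelectionClass:
    def make(self, ratio, saturated=False):
        from apfam.duplication import KaKsResult

        return KaKsResult(1, 2, 0, 0, 0, 0, 0.1, None if ratio is None else ratio * 0.1,
                          ratio, saturated, 10)

    def test_classes(self):
        assert selection_class(self.make(0.3)) == "purifying"
        assert selection_class(self.make(1.0)) == "neutral"
        assert selection_class(self.make(2.0)) == "positive"
        assert selection_class(self.make(None, saturated=True)) == "undefined"
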