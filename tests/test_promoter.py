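"""Promoter extraction and IUPAC degenerate element scanning."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apfam.io_model import GeneModel, GenomeAssembly, GenomeInterval
from apfam.promoter import (
    CIS_ELEMENT_CATALOG,
    IupacMatcher,
    extract_promoter,
    presence_matrix,
    scan_elements,
)

from oracles import scan_oracle


class TestIupacMatcher:
    def test_exact_element_matches_only_itself(self):
        m = IupacMatcher("ACCTACC")
        assert m.matches("ACCTACC")
        assert not m.matches("ACCTACG")

    def test_snbe_degenerate_expansion(self):
        # W={A,T} Y={C,T} B={C,G,T} M={A,C} H={A,C,T}, N = any base
        m = IupacMatcher("WNNYBTNNNNNNNAMGNHW")
        assert m.matches("AAACCTAAAAAAAAAGAAA")

    def test_invalid_code_named_in_error(self):
        with pytest.raises(ValueError, match="J"):
            IupacMatcher("ACJ")

    def test_subject_n_never_matches_even_consensus_n(self):
        m = IupacMatcher("ANA")
        assert m.scan("AAA") == [0]
        assert m.scan("ANA") == []


class TestScanElements:
    def test_plus_strand_hit(self):
        hits = scan_elements("TTACCTACCTT", {"ACI": "ACCTACC"})
        assert [(h.start, h.strand, h.matched) for h in hits] == [(3, "+", "ACCTACC")]

    def test_minus_strand_hit_reported_at_five_prime_coordinate(self):
        # GGTAGGT is the reverse complement of ACCTACC
        hits = scan_elements("TTTGGTAGGTTT", {"ACI": "ACCTACC"})
        assert [(h.start, h.strand, h.matched) for h in hits] == [(4, "-", "GGTAGGT")]

    def test_overlapping_occurrences_all_reported(self):
        hits = scan_elements("ACCTACCTACC", {"ACI": "ACCTACC"}, strands="plus")
        assert [h.start for h in hits] == [1, 5]

    def test_plus_only_mode_misses_minus_hits(self):
        assert scan_elements("TTTGGTAGGTTT", {"ACI": "ACCTACC"}, strands="plus") == []

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            got = {
                (h.element, h.start, h.strand)
                for h in scan_elements(seq, CIS_ELEMENT_CATALOG)
            }
            assert got == scan_oracle(seq, CIS_ELEMENT_CATALOG)

    def test_strand_symmetry(self, rng):
        from apfam.io_model import reverse_complement

        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            fwd = scan_elements(seq, CIS_ELEMENT_CATALOG)
            rev = scan_elements(reverse_complement(seq), CIS_ELEMENT_CATALOG)
            flip = {
                (h.element, len(seq) - (h.start - 1 + len(h.matched)) + 1,
                 "-" if h.strand == "+" else "+")
                for h in rev
            }
            assert {(h.element, h.start, h.strand) for h in fwd} == flip


class TestExtractPromoter:
    def assembly(self, n=10000):
        return GenomeAssembly({"c": "A" * n})

    def gene(self, start, end, strand="+", with_utr5=True):
        exons = [GenomeInterval("c", start, end, strand)]
        utr_len = 50
        if strand == "+":
            utr5 = [GenomeInterval("c", start, start + utr_len, strand)]
            cds = [GenomeInterval("c", start + utr_len, end, strand)]
        else:
            utr5 = [GenomeInterval("c", end - utr_len, end, strand)]
            cds = [GenomeInterval("c", start, end - utr_len, strand)]
        return GeneModel(
            "g", GenomeInterval("c", start, end, strand),
            exons=exons, cds=cds, utr5=utr5 if with_utr5 else [],
        )

    def test_plus_strand_window(self):
        # transcript starts at 1-based 5001 (0-based 5000): promoter 2001..5000
        prom = extract_promoter(self.gene(5000, 6000), self.assembly())
        assert len(prom.sequence) == 3000 and not prom.truncated

    def test_minus_strand_reverse_complement_window(self):
        asm = GenomeAssembly({"c": "A" * 4000 + "CCCC" + "G" * 3000 + "A" * 3000})
        g = self.gene(1000, 4004, strand="-")
        prom = extract_promoter(g, asm)
        assert prom.sequence == "C" * 3000  # revcomp of the G-run after the gene

    def test_truncated_at_chromosome_start(self):
        prom = extract_promoter(self.gene(1499, 2000), self.assembly())
        assert len(prom.sequence) == 1499 and prom.truncated

    def test_no_utr5_anchors_at_cds_start_with_flag(self):
        g = self.gene(5000, 6000, with_utr5=False)
        prom = extract_promoter(g, self.assembly())
        assert prom.anchored_at_cds
        # anchor moved to the CDS start (50 bp into the gene)
        assert len(prom.sequence) == 3000


DNA = st.text(alphabet="ACGTN", min_size=0, max_size=120)


class TestScannerProperties:
    @given(seq=DNA)
    @settings(max_examples=60, derandomize=True)
    def test_scanner_agrees_with_oracle_on_arbitrary_subjects(self, seq):
        got = {
            (h.element, h.start, h.strand)
            for h in scan_elements(seq, CIS_ELEMENT_CATALOG)
        }
        # the oracle's regex classes never include N, so subject N cannot match
        assert got == scan_oracle(seq, CIS_ELEMENT_CATALOG)

    @given(seq=DNA)
    @settings(max_examples=60, derandomize=True)
    def test_minus_hits_are_plus_hits_of_the_reverse_complement(self, seq):
        from apfam.io_model import reverse_complement

        minus = {
            (h.element, h.start)
            for h in scan_elements(seq, CIS_ELEMENT_CATALOG)
            if h.strand == "-"
        }
        transformed = set()
        for h in scan_elements(reverse_complement(seq), CIS_ELEMENT_CATALOG):
            if h.strand == "+":
                end = h.start - 1 + len(h.matched)
                transformed.add((h.element, len(seq) - end + 1))
        assert minus == transformed


class TestPresenceMatrix:
    def test_counts_presence_and_zero_rows(self):
        hits = scan_elements("ACCTACCTACC", {"ACI": "ACCTACC"}, gene_id="g1")
        df = presence_matrix(hits, ["g1", "g2"], {"ACI": "ACCTACC"})
        assert df.loc["g1", "ACI"] == len(hits)
        assert df.loc["g2", "ACI"] == 0
        assert df["ACI"].sum() == len(hits)
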