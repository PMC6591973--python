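"""Tandem/segmental duplication classification, NG86 Ka/Ks and molecular-clock dating.

Tandem duplicates are family genes whose nearest boundaries lie within 50 kb
of one another on a chromosome (single-linkage clusters).  Segmental
duplicates are gene pairs overlapping the two sides of a supplied duplicated
block.  Divergence between duplicate coding sequences is estimated with the
Nei-Gojobori (1986) counting method under the universal code with
Jukes-Cantor multiple-hit correction, and duplication ages follow the
molecular clock T = Ks / (2 lambda) with lambda = 9.1e-9 synonymous
substitutions per site per year for *Populus*.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_model import GenomeInterval

__all__ = [
    "DuplicationBlockTable",
    "KaKsResult",
    "DuplicationPair",
    "find_tandem",
    "assign_segmental",
    "codon_align",
    "ng86",
    "date_duplication",
    "selection_class",
    "POPULUS_LAMBDA",
]

POPULUS_LAMBDA = 9.1e-9  # synonymous substitutions / site / year

BASES = "ACGT"
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOPS = frozenset(standard_dna_table.stop_codons)


def _syn_site_fraction(codon: str) -> float:
    """NG86 synonymous-site count of one codon (0..3).

    Each position contributes the fraction of its single-nucleotide changes
    that are synonymous, with changes to stop codons excluded from both
    numerator and denominator.
    """
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            valid += 1
            syn += CODON_TO_AA[alt] == aa
        if valid:
            total += syn / valid
    return total


_SYN_FRACTION = {c: _syn_site_fraction(c) for c in CODON_TO_AA if c not in STOPS}


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal mutational pathways whose intermediates avoid
    stop codons; if every pathway passes through a stop the average falls back
    to all minimal pathways.
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = a
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS and nxt != b:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(CODON_TO_AA[x] == CODON_TO_AA[y] for x, y in steps)
        paths.append((through_stop, syn, len(steps) - syn))
    usable = [p for p in paths if not p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0  # +0.0 avoids -0.0


@dataclass
class KaKsResult:
    S_sites: float
    N_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    saturated: bool
    n_codons: int
    n_dropped: int = 0


@dataclass
class CodonAlignment:
    pairs: list[tuple[str, str]]
    n_dropped: int = 0  # codon pairs removed because they contained N


def codon_align(
    cds_a: str,
    cds_b: str,
    protein_aln: Optional[tuple[str, str]] = None,
) -> CodonAlignment:
    """Map a protein pairwise alignment back onto codons.

    Trailing stop codons are stripped; gap columns are dropped; codon pairs
    containing N are dropped with the count recorded.  When no protein
    alignment is given one is computed with the default global aligner.
    """

    def strip_stop(cds: str) -> str:
        if len(cds) % 3 == 0 and cds[-3:] in STOPS:
            return cds[:-3]
        return cds

    cds_a, cds_b = strip_stop(cds_a.upper()), strip_stop(cds_b.upper())
    for cds in (cds_a, cds_b):
        if len(cds) % 3 != 0:
            raise ValueError("CDS length not a multiple of 3 after stop stripping")
    if protein_aln is None:
        from Bio.Seq import Seq

        from .phylogeny import pairwise_align

        pa = pairwise_align(str(Seq(cds_a).translate()), str(Seq(cds_b).translate()))
        protein_aln = (pa.aligned_a, pa.aligned_b)
    ra, rb = protein_aln
    if len(ra.replace("-", "")) * 3 != len(cds_a) or len(
        rb.replace("-", "")
    ) * 3 != len(cds_b):
        raise ValueError("protein alignment length does not match CDS length")
    pairs, dropped = [], 0
    ia = ib = 0
    for x, y in zip(ra, rb):
        ca = cds_a[3 * ia : 3 * ia + 3] if x != "-" else None
        cb = cds_b[3 * ib : 3 * ib + 3] if y != "-" else None
        ia += x != "-"
        ib += y != "-"
        if ca is None or cb is None:
            continue
        if "N" in ca or "N" in cb:
            dropped += 1
            continue
        pairs.append((ca, cb))
    return CodonAlignment(pairs, dropped)


def ng86(codon_pairs, n_dropped: int = 0) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Synonymous-site fractions are averaged over the two sequences;
    multi-nucleotide codon differences are averaged over all minimal stop-free
    mutational pathways.  The result is flagged saturated (Ks/Ka undefined)
    when ps or pn reaches 3/4.
    """
    if isinstance(codon_pairs, CodonAlignment):
        n_dropped += codon_pairs.n_dropped
        codon_pairs = codon_pairs.pairs
    pairs = []
    for a, b in codon_pairs:
        a, b = a.upper(), b.upper()
        if a in STOPS or b in STOPS:
            n_dropped += 1
            continue
        pairs.append((a, b))
    if not pairs:
        raise ValueError("no usable codon pairs")
    Sa = sum(_SYN_FRACTION[a] for a, _ in pairs)
    Sb = sum(_SYN_FRACTION[b] for _, b in pairs)
    S = 0.5 * (Sa + Sb)
    N = 3.0 * len(pairs) - S
    sd = nd = 0.0
    for a, b in pairs:
        s, n = _pathway_counts(a, b)
        sd += s
        nd += n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    Ks = None if saturated else _jukes_cantor(ps)
    Ka = None if saturated else _jukes_cantor(pn)
    ratio = None
    if Ks is not None and Ka is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        S_sites=S,
        N_sites=N,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        saturated=saturated,
        n_codons=len(pairs),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Duplication classification
# ---------------------------------------------------------------------------


def find_tandem(
    members: Iterable[tuple[str, GenomeInterval]], window_bp: int = 50000
) -> list[list[str]]:
    """Single-linkage clusters of family genes within `window_bp` of one another.

    Distance is the gap between nearest gene boundaries on the same
    chromosome; clusters of size >= 2 are reported, ordered by position.
    """
    by_chrom: dict[str, list[tuple[str, GenomeInterval]]] = {}
    for gid, iv in members:
        by_chrom.setdefault(iv.chrom, []).append((gid, iv))
    clusters = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda t: (t[1].start, t[0]))
        current = [genes[0]]
        for prev, nxt in zip(genes, genes[1:]):
            if prev[1].gap_to(nxt[1]) <= window_bp:
                current.append(nxt)
            else:
                if len(current) >= 2:
                    clusters.append([g for g, _ in current])
                current = [nxt]
        if len(current) >= 2:
            clusters.append([g for g, _ in current])
    return clusters


@dataclass
class DuplicationBlockTable:
    """Paired duplicated chromosome segments (e.g., PGDD-style blocks)."""

    rows: list[tuple[str, GenomeInterval, GenomeInterval]] = field(
        default_factory=list
    )

    @classmethod
    def read_tsv(cls, path) -> "DuplicationBlockTable":
        df = pd.read_csv(path, sep="\t")
        rows = []
        for _, r in df.iterrows():
            rows.append(
                (
                    str(r["block_id"]),
                    GenomeInterval(r["chromA"], int(r["startA"]) - 1, int(r["endA"])),
                    GenomeInterval(r["chromB"], int(r["startB"]) - 1, int(r["endB"])),
                )
            )
        return cls(rows)

    def to_tsv(self, path) -> None:
        recs = [
            {
                "block_id": bid,
                "chromA": a.chrom,
                "startA": a.start + 1,
                "endA": a.end,
                "chromB": b.chrom,
                "startB": b.start + 1,
                "endB": b.end,
            }
            for bid, a, b in self.rows
        ]
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def assign_segmental(
    members: Iterable[tuple[str, GenomeInterval]],
    blocks: DuplicationBlockTable,
) -> list[tuple[str, str, str]]:
    """Gene pairs supported by a duplicated block (>= 1 bp overlap each side).

    Returns (gene_a, gene_b, block_id) with gene_a < gene_b; a gene alone on
    one side of a block yields no pair.
    """
    members = list(members)
    out = []
    seen = set()
    for bid, iva, ivb in blocks.rows:
        in_a = [g for g, iv in members if iv.overlaps(iva)]
        in_b = [g for g, iv in members if iv.overlaps(ivb)]
        for ga in in_a:
            for gb in in_b:
                if ga == gb:
                    continue
                key = tuple(sorted((ga, gb)))
                if key not in seen:
                    seen.add(key)
                    out.append((key[0], key[1], bid))
    return out


def date_duplication(Ks: float, lambda_rate: float = POPULUS_LAMBDA) -> float:
    """Molecular-clock age in years: T = Ks / (2 lambda)."""
    if Ks < 0:
        raise ValueError("Ks must be non-negative")
    return Ks / (2.0 * lambda_rate)


def selection_class(result: KaKsResult) -> str:
    if result.ratio is None:
        return "undefined"
    if result.ratio < 1.0:
        return "purifying"
    if result.ratio == 1.0:
        return "neutral"
    return "positive"


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    dtype: str  # tandem | segmental
    kaks: Optional[KaKsResult] = None
    T_years: Optional[float] = None
    T_mya: Optional[float] = None
    selection: str = "undefined"


def analyze_duplications(
    intervals: dict[str, GenomeInterval],
    cds: dict[str, str],
    blocks: Optional[DuplicationBlockTable] = None,
    tandem_window_bp: int = 50000,
    lambda_rate: float = POPULUS_LAMBDA,
) -> tuple[list[list[str]], list[DuplicationPair]]:
    """Full duplication analysis: tandem clusters, block pairs, Ka/Ks and ages."""
    members = list(intervals.items())
    clusters = find_tandem(members, tandem_window_bp)
    pair_specs: list[tuple[str, str, str]] = []
    seen = set()
    for cluster in clusters:
        for ga, gb in itertools.combinations(cluster, 2):
            key = tuple(sorted((ga, gb)))
            seen.add(key)
            pair_specs.append((key[0], key[1], "tandem"))
    if blocks is not None:
        for ga, gb, _bid in assign_segmental(members, blocks):
            if (ga, gb) not in seen:
                seen.add((ga, gb))
                pair_specs.append((ga, gb, "segmental"))
    pairs = []
    for ga, gb, dtype in pair_specs:
        dp = DuplicationPair(ga, gb, dtype)
        if ga in cds and gb in cds:
            dp.kaks = ng86(codon_align(cds[ga], cds[gb]))
            if dp.kaks.Ks is not None:
                dp.T_years = date_duplication(dp.kaks.Ks, lambda_rate)
                dp.T_mya = dp.T_years / 1e6
            dp.selection = selection_class(dp.kaks)
        pairs.append(dp)
    return clusters, pairs


def pairs_to_frame(pairs: Iterable[DuplicationPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        k = p.kaks
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "dtype": p.dtype,
                "Ka": None if k is None else k.Ka,
                "Ks": None if k is None else k.Ks,
                "ratio": None if k is None else k.ratio,
                "T_mya": p.T_mya,
                "selection_class": p.selection,
                "saturated": False if k is None else k.saturated,
            }
        )
    return pd.DataFrame(rows)
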