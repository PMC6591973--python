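"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own lookup tables and vectorized
paths: translation goes through Biopython, site counting enumerates every
single-nucleotide neighbor explicitly, pathway counting enumerates
permutations, and motif scanning expands IUPAC codes into regex classes.
"""

import itertools
import re
from functools import lru_cache

from Bio.Seq import Seq

BASES = "ACGT"

IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@lru_cache(maxsize=None)
def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa(codon) == "*"


def ng86_oracle(codon_pairs):
    """Brute-force NG86: explicit neighbor enumeration + pathway enumeration.

    Returns (S, N, sd, nd, ps, pn, Ks, Ka) with None for saturated/undefined.
    """
    import math

    def syn_sites(codon):
        total = 0.0
        for pos in range(3):
            syn = valid = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if is_stop(alt):
                    continue
                valid += 1
                if aa(alt) == aa(codon):
                    syn += 1
            if valid:
                total += syn / valid
        return total

    def pair_diffs(a, b):
        positions = [i for i in range(3) if a[i] != b[i]]
        if not positions:
            return 0.0, 0.0
        results = []
        for order in itertools.permutations(positions):
            cur, steps, blocked = a, [], False
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if is_stop(nxt) and nxt != b:
                    blocked = True
                steps.append((cur, nxt))
                cur = nxt
            syn = sum(1 for x, y in steps if aa(x) == aa(y))
            results.append((blocked, syn, len(steps) - syn))
        open_paths = [r for r in results if not r[0]] or results
        sd = sum(r[1] for r in open_paths) / len(open_paths)
        nd = sum(r[2] for r in open_paths) / len(open_paths)
        return sd, nd

    S = sum(0.5 * (syn_sites(a) + syn_sites(b)) for a, b in codon_pairs)
    N = 3 * len(codon_pairs) - S
    sd = nd = 0.0
    for a, b in codon_pairs:
        s, n = pair_diffs(a, b)
        sd += s
        nd += n
    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return S, N, sd, nd, ps, pn, None, None
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return S, N, sd, nd, ps, pn, jc(ps), jc(pn)


def iupac_regex_hits(sequence, consensus):
    """Plus-strand hit offsets via a regex expansion of the consensus."""
    pattern = "".join(f"[{IUPAC_EXPANSION[c]}]" for c in consensus.upper())
    return [m.start() for m in re.finditer(f"(?=({pattern}))", sequence.upper())]


def scan_oracle(sequence, catalog, strands="both"):
    """Full both-strand oracle: set of (element, 1-based start, strand)."""
    hits = set()
    for name, consensus in catalog.items():
        for off in iupac_regex_hits(sequence, consensus):
            hits.add((name, off + 1, "+"))
        if strands == "both":
            rc = str(Seq(consensus).reverse_complement())
            for off in iupac_regex_hits(sequence, rc):
                hits.add((name, off + 1, "-"))
    return hits


def random_stop_free_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if not is_stop(c):
            codons.append(c)
    return "".join(codons)


def sequon_oracle(protein):
    """Triple-window brute force for N-X-[S/T], X != P."""
    out = []
    for i in range(len(protein)):
        if i + 2 < len(protein):
            n, x, st = protein[i], protein[i + 1], protein[i + 2]
            if n == "N" and x != "P" and st in ("S", "T"):
                out.append(i + 1)
    return out
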