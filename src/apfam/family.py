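"""Rule-based identification and categorization of aspartic-protease family members.

Pepsin-like aspartic proteases (EC 3.4.23) carry two catalytic Asp residues
inside conserved Asp-Thr/Ser-Gly (D[TS]G) motifs.  A candidate protein is a
family member here when it has a perfect ORF and a "complete domain": two
D[TS]G hits whose Asp positions are separated by a plausible spacing
(defaults 100-350 residues).  Members are categorized:

* **A** (typical APs) — a plant-specific insert (PSI): a saposin-like,
  cysteine-rich segment between the catalytic motifs, detected as >= 6 Cys in
  a 120-residue window strictly between the two chosen Asp positions;
* **B** (nucellin-like APs) — both QCDYE and GCGYDQ conserved sequences
  present (<= 1 substitution each by default);
* **C** (atypical APs) — everything else.

A matches take precedence over B; a protein satisfying both is assigned A and
flagged as a conflict.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

__all__ = [
    "ORFReport",
    "CatalyticMotifHit",
    "FamilyMember",
    "check_orf",
    "find_catalytic_motifs",
    "domain_complete",
    "fuzzy_find",
    "has_psi_insert",
    "classify_category",
    "compute_mw",
    "majority_vote_localization",
    "build_member",
    "identify_family",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

# ExPASy average residue masses (Da); MW = sum + one water.
WATER_MASS = 18.0153
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

NUCELLIN_MOTIFS = ("QCDYE", "GCGYDQ")


class ORFReport(NamedTuple):
    starts_with_atg: bool
    ends_with_stop: bool
    no_internal_stop: bool
    frame_ok: bool

    @property
    def perfect(self) -> bool:
        return all(self)


def check_orf(cds: str) -> ORFReport:
    """Flag the four conditions of a perfect open reading frame."""
    if not cds:
        raise ValueError("empty CDS")
    cds = cds.upper()
    frame_ok = len(cds) % 3 == 0
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    starts = cds.startswith("ATG")
    ends = frame_ok and bool(codons) and codons[-1] in STOP_CODONS
    internal = any(c in STOP_CODONS for c in codons[:-1])
    return ORFReport(starts, ends, not internal, frame_ok)


class CatalyticMotifHit(NamedTuple):
    position: int  # 1-based residue index of the catalytic Asp
    triplet: str


def find_catalytic_motifs(protein: str) -> list[CatalyticMotifHit]:
    """All D[TS]G occurrences, in order (overlapping starts impossible for this motif)."""
    hits = []
    for i in range(len(protein) - 2):
        if (
            protein[i] == "D"
            and protein[i + 1] in "TS"
            and protein[i + 2] == "G"
        ):
            hits.append(CatalyticMotifHit(i + 1, protein[i : i + 3]))
    return hits


def domain_complete(
    hits: list[CatalyticMotifHit], min_gap: int = 100, max_gap: int = 350
) -> tuple[bool, Optional[tuple[CatalyticMotifHit, CatalyticMotifHit]]]:
    """True iff some pair of catalytic Asp positions is spaced within [min_gap, max_gap].

    The chosen pair is the first in (leftmost first Asp, leftmost partner) order.
    """
    for i, a in enumerate(hits):
        for b in hits[i + 1 :]:
            if min_gap <= b.position - a.position <= max_gap:
                return True, (a, b)
    return False, None


def fuzzy_find(protein: str, motif: str, max_mismatch: int = 1) -> Optional[int]:
    """1-based start of the best (fewest-mismatch, leftmost) match, or None."""
    best = None
    best_mm = max_mismatch + 1
    for i in range(len(protein) - len(motif) + 1):
        mm = sum(1 for a, b in zip(protein[i : i + len(motif)], motif) if a != b)
        if mm < best_mm:
            best, best_mm = i + 1, mm
            if mm == 0:
                break
    return best if best_mm <= max_mismatch else None


def has_psi_insert(
    protein: str,
    pair: tuple[CatalyticMotifHit, CatalyticMotifHit],
    min_cys: int = 6,
    window: int = 120,
) -> bool:
    """Cys-rich PSI heuristic: >= min_cys C's in a window strictly between the Asps.

    When the inter-Asp region is shorter than `window` the whole region serves
    as the single window.
    """
    a, b = pair
    region = protein[a.position : b.position - 1]  # strictly between (1-based)
    if not region:
        return False
    w = min(window, len(region))
    count = region[:w].count("C")
    best = count
    for i in range(len(region) - w):
        count += (region[i + w] == "C") - (region[i] == "C")
        best = max(best, count)
    return best >= min_cys


def classify_category(
    protein: str,
    pair: tuple[CatalyticMotifHit, CatalyticMotifHit],
    max_motif_mismatch: int = 1,
    psi_min_cys: int = 6,
    psi_window: int = 120,
) -> tuple[str, bool]:
    """Assign category A/B/C for a domain-complete protein.

    Returns (category, conflict) where conflict marks proteins matching both
    the PSI rule (A) and the nucellin motifs (B); A takes precedence.
    """
    is_a = has_psi_insert(protein, pair, psi_min_cys, psi_window)
    is_b = all(
        fuzzy_find(protein, m, max_motif_mismatch) is not None
        for m in NUCELLIN_MOTIFS
    )
    if is_a:
        return "A", is_b
    if is_b:
        return "B", False
    return "C", False


def compute_mw(protein: str) -> float:
    """Average-mass molecular weight in daltons, to 2 decimals."""
    if not protein:
        raise ValueError("empty protein")
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return round(mass + WATER_MASS, 2)


def majority_vote_localization(predictions: list[str]) -> str:
    """Strict-majority consensus of subcellular-localization labels."""
    if not predictions:
        raise ValueError("no predictions")
    label, count = Counter(predictions).most_common(1)[0]
    return label if 2 * count > len(predictions) else "ambiguous"


@dataclass
class FamilyMember:
    gene_id: str
    protein: str
    orf_complete: bool
    domain_complete: bool
    catalytic_hits: list[CatalyticMotifHit] = field(default_factory=list)
    chosen_pair: Optional[tuple[CatalyticMotifHit, CatalyticMotifHit]] = None
    category: str = "unassigned"
    category_conflict: bool = False
    mw_da: float = 0.0
    localization_consensus: str = "ambiguous"


def build_member(
    gene_id: str,
    cds: str,
    protein: str,
    localizations: Optional[list[str]] = None,
    min_gap: int = 100,
    max_gap: int = 350,
    max_motif_mismatch: int = 1,
) -> FamilyMember:
    """Run the full identification rule chain on one candidate."""
    orf = check_orf(cds)
    hits = find_catalytic_motifs(protein)
    complete, pair = domain_complete(hits, min_gap, max_gap)
    category, conflict = "unassigned", False
    if complete:
        category, conflict = classify_category(protein, pair, max_motif_mismatch)
    return FamilyMember(
        gene_id=gene_id,
        protein=protein,
        orf_complete=orf.perfect,
        domain_complete=complete,
        catalytic_hits=hits,
        chosen_pair=pair,
        category=category,
        category_conflict=conflict,
        mw_da=compute_mw(protein) if protein else 0.0,
        localization_consensus=(
            majority_vote_localization(localizations) if localizations else "ambiguous"
        ),
    )


def identify_family(
    cds_seqs: dict[str, str],
    proteins: dict[str, str],
    localizations: Optional[dict[str, list[str]]] = None,
    **rule_kwargs,
) -> list[FamilyMember]:
    """Apply :func:`build_member` to every candidate with both CDS and protein."""
    members = []
    for gid in cds_seqs:
        if gid not in proteins:
            continue
        locs = (localizations or {}).get(gid)
        members.append(
            build_member(gid, cds_seqs[gid], proteins[gid], locs, **rule_kwargs)
        )
    return members


def confirmed_members(members: Iterable[FamilyMember]) -> list[FamilyMember]:
    """Members with a perfect ORF and a complete domain (the paper-style family set)."""
    return [m for m in members if m.orf_complete and m.domain_complete]
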