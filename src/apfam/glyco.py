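"""N-glycosylation sequon detection and placement relative to category-B anchors.

The canonical acceptor sequon is N-X-[S/T] with X != P.  For nucellin-like
(category B) members the conserved site of interest lies upstream of the
GCGYDQ anchor motif; the pepsin-numbering Tyr75 bound is operationalized as a
fixed-size window upstream of that anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from .family import fuzzy_find

__all__ = ["SequonHit", "ConservedSequonCall", "scan_n_sequons",
           "conserved_sequon_between_anchors"]

GCGYDQ = "GCGYDQ"


class SequonHit(NamedTuple):
    position: int  # 1-based index of the N
    triplet: str
    context: str  # +/- 5 residues around the sequon


def scan_n_sequons(protein: str) -> list[SequonHit]:
    """All N-X-[S/T] (X != P) sequons, overlapping ones included."""
    protein = protein.upper()
    hits = []
    for i in range(len(protein) - 2):
        if (
            protein[i] == "N"
            and protein[i + 1] != "P"
            and protein[i + 2] in "ST"
        ):
            lo = max(0, i - 5)
            hits.append(
                SequonHit(i + 1, protein[i : i + 3], protein[lo : i + 8])
            )
    return hits


@dataclass
class ConservedSequonCall:
    status: str  # found | absent | anchor-missing | not-applicable
    position: Optional[int] = None  # 1-based sequon position when found
    anchor_start: Optional[int] = None

    @property
    def found(self) -> bool:
        return self.status == "found"


def conserved_sequon_between_anchors(
    protein: str,
    category: str,
    upstream_window: int = 60,
    max_anchor_mismatch: int = 1,
) -> ConservedSequonCall:
    """Category-B conserved-sequon call: a sequon within `upstream_window`
    residues 5' of the GCGYDQ anchor."""
    if category != "B":
        return ConservedSequonCall("not-applicable")
    anchor = fuzzy_find(protein.upper(), GCGYDQ, max_anchor_mismatch)
    if anchor is None:
        return ConservedSequonCall("anchor-missing")
    for hit in scan_n_sequons(protein):
        if anchor - upstream_window <= hit.position < anchor:
            return ConservedSequonCall("found", hit.position, anchor)
    return ConservedSequonCall("absent", None, anchor)
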