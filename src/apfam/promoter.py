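"""3-kb promoter extraction and IUPAC degenerate scanning for SCW cis-elements.

The built-in catalog holds the ten secondary-cell-wall / xylem-PCD elements
(SNBE, TERE, M46RE, the AC elements and the SMREs) as IUPAC consensus
strings.  Matching is exact set membership per position: a consensus code
matches the subject bases in its IUPAC expansion, and an N in the *subject*
never matches anything (masked sequence cannot fire a hit).  Both strands are
scanned by default; minus-strand hits are matches of the reverse-complement
pattern reported at their 5'-most promoter coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io_model import GeneModel, GenomeAssembly, reverse_complement

__all__ = [
    "CIS_ELEMENT_CATALOG",
    "CisElementHit",
    "PromoterSequence",
    "IupacMatcher",
    "iupac_matcher",
    "extract_promoter",
    "scan_elements",
    "presence_matrix",
    "read_catalog_tsv",
]

# Secondary-cell-wall-related cis-elements (name -> IUPAC consensus)
CIS_ELEMENT_CATALOG: dict[str, str] = {
    "SNBE": "WNNYBTNNNNNNNAMGNHW",
    "TERE": "CTTNAAAGCNA",
    "M46RE": "RKTWGGTR",
    "ACI": "ACCTACC",
    "ACII": "ACCAACC",
    "ACIII": "ACCTAAC",
    "SMRE1": "ACCAAAT",
    "SMRE2": "ACCAACT",
    "SMRE3": "ACCAAAC",
    "SMRE5": "ACCTAAT",
}

IUPAC_SETS: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT_CODE = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

# 2-bit-per-base encoding; subject N encodes to 0 so it can never satisfy a mask
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 0}
_ENCODE = np.zeros(256, dtype=np.uint8)
for _b, _v in _BASE_BITS.items():
    _ENCODE[ord(_b)] = _v


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, [ord(b) for b in _BASE_BITS])
    if bad.any():
        raise ValueError(
            f"subject sequence contains non-ACGTN character "
            f"{chr(arr[np.argmax(bad)])!r}"
        )
    return _ENCODE[arr]


class IupacMatcher:
    """Compiled degenerate consensus; finds all (overlapping) match offsets."""

    def __init__(self, consensus: str):
        consensus = consensus.upper()
        for ch in consensus:
            if ch not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC code {ch!r} in consensus")
        self.consensus = consensus
        self._mask = np.array(
            [sum(_BASE_BITS[b] for b in IUPAC_SETS[c]) for c in consensus],
            dtype=np.uint8,
        )

    def __len__(self) -> int:
        return len(self.consensus)

    def matches(self, s: str) -> bool:
        if len(s) != len(self.consensus):
            return False
        return bool(self.scan(s)) if s else False

    def scan(self, subject: str) -> list[int]:
        """0-based start offsets of every match (overlaps included)."""
        L = len(self._mask)
        if len(subject) < L:
            return []
        enc = _encode(subject.upper())
        win = np.lib.stride_tricks.sliding_window_view(enc, L)
        ok = ((win & self._mask) == win) & (win != 0)
        return np.flatnonzero(ok.all(axis=1)).tolist()

    def reverse_complement(self) -> "IupacMatcher":
        rc = "".join(_COMPLEMENT_CODE[c] for c in reversed(self.consensus))
        return IupacMatcher(rc)


def iupac_matcher(consensus: str) -> IupacMatcher:
    return IupacMatcher(consensus)


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element: str
    start: int  # 1-based position within the promoter, 5'->3' toward the gene
    strand: str
    matched: str


@dataclass
class PromoterSequence:
    gene_id: str
    sequence: str  # 5'->3' on the gene's coding strand
    truncated: bool
    anchored_at_cds: bool  # no annotated 5'UTR; anchor fell back to the CDS start


def extract_promoter(
    gene: GeneModel, assembly: GenomeAssembly, length_bp: int = 3000
) -> PromoterSequence:
    """Upstream window of the transcription start, on the coding strand.

    The anchor is the 5'-most transcript coordinate (3'-most genomic for
    minus-strand genes); genes lacking an annotated 5'UTR anchor at the CDS
    start and carry a flag.  The window is truncated at the chromosome edge.
    """
    if not gene.exons and not gene.cds:
        raise ValueError(f"{gene.gene_id}: no features to anchor a promoter")
    anchored_at_cds = not gene.utr5
    segs = gene.exons or gene.cds
    if anchored_at_cds and gene.cds:
        segs = gene.cds
    chrom_len = assembly.length(gene.interval.chrom)
    if gene.strand == "+":
        tss = min(s.start for s in segs)
        lo = max(0, tss - length_bp)
        seq = assembly[gene.interval.chrom][lo:tss]
        truncated = tss - length_bp < 0
    else:
        tss_end = max(s.end for s in segs)  # half-open end; promoter starts here
        hi = min(chrom_len, tss_end + length_bp)
        seq = reverse_complement(assembly[gene.interval.chrom][tss_end:hi])
        truncated = tss_end + length_bp > chrom_len
    return PromoterSequence(gene.gene_id, seq, truncated, anchored_at_cds)


def scan_elements(
    promoter: str,
    catalog: Optional[dict[str, str]] = None,
    strands: str = "both",
    gene_id: str = "",
) -> list[CisElementHit]:
    """Every occurrence of every catalog element at every offset.

    Overlapping hits are all reported.  Minus-strand hits are reported at the
    hit's 5'-most promoter coordinate with the promoter-strand substring as
    ``matched`` (its reverse complement satisfies the consensus).
    """
    if strands not in ("plus", "both"):
        raise ValueError(f"unknown strand mode {strands!r}")
    catalog = catalog if catalog is not None else CIS_ELEMENT_CATALOG
    promoter = promoter.upper()
    hits = []
    for name, consensus in catalog.items():
        m = IupacMatcher(consensus)
        for off in m.scan(promoter):
            hits.append(
                CisElementHit(gene_id, name, off + 1, "+", promoter[off : off + len(m)])
            )
        if strands == "both":
            rc = m.reverse_complement()
            for off in rc.scan(promoter):
                hits.append(
                    CisElementHit(
                        gene_id, name, off + 1, "-", promoter[off : off + len(m)]
                    )
                )
    hits.sort(key=lambda h: (h.start, h.element, h.strand))
    return hits


def presence_matrix(
    hits: Iterable[CisElementHit],
    genes: Iterable[str],
    catalog: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Gene x element hit-count table (presence = count >= 1); all genes retained."""
    catalog = catalog if catalog is not None else CIS_ELEMENT_CATALOG
    df = pd.DataFrame(0, index=list(genes), columns=list(catalog), dtype=int)
    for h in hits:
        if h.gene_id in df.index and h.element in df.columns:
            df.loc[h.gene_id, h.element] += 1
    return df


def read_catalog_tsv(path) -> dict[str, str]:
    """Two-column (name, consensus) TSV overriding the built-in catalog."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "consensus"])
    catalog = {}
    for _, r in df.iterrows():
        name = str(r["name"])
        if name in catalog:
            raise ValueError(f"duplicate element name {name}")
        IupacMatcher(str(r["consensus"]))  # validates alphabet
        catalog[name] = str(r["consensus"]).upper()
    return catalog


def hits_to_bed_frame(hits: Iterable[CisElementHit]) -> pd.DataFrame:
    """BED-like table: gene as contig surrogate, 0-based half-open coordinates."""
    rows = [
        {
            "gene_id": h.gene_id,
            "start": h.start - 1,
            "end": h.start - 1 + len(h.matched),
            "name": h.element,
            "strand": h.strand,
            "matched": h.matched,
        }
        for h in hits
    ]
    return pd.DataFrame(rows)
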