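"""Exon/intron arrangement statistics and structural flags per family gene."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .io_model import GeneModel

__all__ = ["StructureReport", "structure_report", "family_structure_summary"]


@dataclass
class StructureReport:
    gene_id: str
    n_exons: int
    n_introns: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    has_utr5: bool
    has_utr3: bool
    intronless: bool


def structure_report(gene: GeneModel) -> StructureReport:
    """Per-gene exon/intron lengths (bp) and UTR/intronless flags.

    Introns span between consecutive exons in genomic order; a gene is
    intronless iff its selected transcript has a single exon.
    """
    exons = gene.exons
    if not exons:
        raise ValueError(f"{gene.gene_id}: no exons")
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValueError(f"{gene.gene_id}: overlapping exons")
    exon_lengths = [len(e) for e in exons]
    intron_lengths = [b.start - a.end for a, b in zip(exons, exons[1:])]
    return StructureReport(
        gene_id=gene.gene_id,
        n_exons=len(exons),
        n_introns=len(exons) - 1,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        has_utr5=bool(gene.utr5),
        has_utr3=bool(gene.utr3),
        intronless=len(exons) == 1,
    )


def family_structure_summary(
    reports: Iterable[StructureReport],
    categories: Optional[dict[str, str]] = None,
) -> dict:
    """Family-level counts: intronless genes, genes lacking a 5'UTR, and the
    per-category exon-count range."""
    reports = list(reports)
    summary: dict = {
        "n_genes": len(reports),
        "n_intronless": sum(r.intronless for r in reports),
        "n_lacking_utr5": sum(not r.has_utr5 for r in reports),
        "exon_count_range": (
            (min(r.n_exons for r in reports), max(r.n_exons for r in reports))
            if reports
            else None
        ),
        "per_category": {},
    }
    if categories:
        by_cat: dict[str, list[int]] = {}
        for r in reports:
            cat = categories.get(r.gene_id)
            if cat is not None:
                by_cat.setdefault(cat, []).append(r.n_exons)
        summary["per_category"] = {
            cat: {"n": len(v), "exon_count_range": (min(v), max(v))}
            for cat, v in sorted(by_cat.items())
        }
    return summary


def reports_to_frame(reports: Iterable[StructureReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "gene_id": r.gene_id,
                "n_exons": r.n_exons,
                "n_introns": r.n_introns,
                "exon_lengths": ",".join(map(str, r.exon_lengths)),
                "intron_lengths": ",".join(map(str, r.intron_lengths)),
                "has_utr5": r.has_utr5,
                "has_utr3": r.has_utr3,
                "intronless": r.intronless,
            }
        )
    return pd.DataFrame(rows)
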