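"""End-to-end orchestration of the family-characterization stages.

The analysis scripts, the CLI and the acceptance harness all drive the
library through this module so that a run is reproducible from a single
config (plain ``key = value`` text; CLI flags win over the file).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import (
    duplication,
    expression as expr,
    family,
    gene_structure,
    glyco,
    io_model,
    phylogeny,
    promoter,
)

__all__ = ["PipelineConfig", "PipelineInputs", "run_all"]


@dataclass
class PipelineConfig:
    """Stage parameters; the defaults are the published analysis parameters."""

    promoter_length: int = 3000
    tandem_window: int = 50000
    lambda_rate: float = 9.1e-9
    efp_threshold: float = 1000.0
    min_gap: int = 100
    max_gap: int = 350
    max_motif_mismatch: int = 1
    strands: str = "both"
    bootstrap_reps: int = 1000
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    def override(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass
class PipelineInputs:
    genome: Optional[str] = None
    gff: Optional[str] = None
    proteins: Optional[str] = None
    cds: Optional[str] = None
    blocks: Optional[str] = None
    expression: Optional[str] = None
    alignment: Optional[str] = None

    def require(self, *names) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None:
                raise FileNotFoundError(f"missing required input: --{name}")
            if not Path(path).exists():
                raise FileNotFoundError(f"missing required input file: {path}")


def run_all(
    inputs: PipelineInputs, outdir, config: Optional[PipelineConfig] = None
) -> dict:
    """Run every stage the inputs allow; write stage tables under ``outdir``
    and return the consolidated report dictionary."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {f.name: getattr(config, f.name) for f in fields(config)}}

    inputs.require("genome", "gff")
    assembly = io_model.read_fasta(inputs.genome)
    genes = io_model.read_gff3(inputs.gff, assembly)
    gene_by_id = {g.gene_id: g for g in genes}

    if inputs.cds and Path(inputs.cds).exists():
        cds_seqs = io_model.read_sequences(inputs.cds)
    else:
        cds_seqs = {g.gene_id: io_model.extract_cds(g, assembly) for g in genes}
    if inputs.proteins and Path(inputs.proteins).exists():
        proteins = io_model.read_sequences(inputs.proteins)
    else:
        proteins = {gid: io_model.translate(s).protein for gid, s in cds_seqs.items()}

    # --- identification and categorization ---
    members = family.identify_family(
        cds_seqs,
        proteins,
        min_gap=config.min_gap,
        max_gap=config.max_gap,
        max_motif_mismatch=config.max_motif_mismatch,
    )
    confirmed = family.confirmed_members(members)
    members_df = pd.DataFrame(
        {
            "gene_id": m.gene_id,
            "orf_complete": m.orf_complete,
            "domain_complete": m.domain_complete,
            "catalytic_positions": ",".join(
                str(h.position) for h in m.catalytic_hits
            ),
            "category": m.category,
            "mw_da": m.mw_da,
            "localization_consensus": m.localization_consensus,
        }
        for m in members
    )
    members_df.to_csv(outdir / "members.tsv", sep="\t", index=False)
    categories = {m.gene_id: m.category for m in confirmed}
    report["identification"] = {
        "n_candidates": len(members),
        "n_confirmed": len(confirmed),
        "category_counts": {
            c: sum(1 for m in confirmed if m.category == c) for c in "ABC"
        },
    }

    # --- gene structure ---
    reports = [
        gene_structure.structure_report(gene_by_id[m.gene_id])
        for m in confirmed
        if m.gene_id in gene_by_id
    ]
    gene_structure.reports_to_frame(reports).to_csv(
        outdir / "structure.tsv", sep="\t", index=False
    )
    report["structure"] = gene_structure.family_structure_summary(reports, categories)

    # --- duplication and dating ---
    intervals = {
        m.gene_id: gene_by_id[m.gene_id].interval
        for m in confirmed
        if m.gene_id in gene_by_id
    }
    blocks = None
    if inputs.blocks and Path(inputs.blocks).exists():
        blocks = duplication.DuplicationBlockTable.read_tsv(inputs.blocks)
    clusters, pairs = duplication.analyze_duplications(
        intervals,
        cds_seqs,
        blocks,
        tandem_window_bp=config.tandem_window,
        lambda_rate=config.lambda_rate,
    )
    duplication.pairs_to_frame(pairs).to_csv(
        outdir / "duplication_pairs.tsv", sep="\t", index=False
    )
    report["duplication"] = {
        "tandem_clusters": clusters,
        "n_pairs": len(pairs),
        "pairs": [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "dtype": p.dtype,
                "Ks": None if p.kaks is None else p.kaks.Ks,
                "Ka": None if p.kaks is None else p.kaks.Ka,
                "ratio": None if p.kaks is None else p.kaks.ratio,
                "T_mya": p.T_mya,
                "selection_class": p.selection,
            }
            for p in pairs
        ],
    }

    # --- promoter cis-element scan ---
    all_hits = []
    for m in confirmed:
        gene = gene_by_id.get(m.gene_id)
        if gene is None:
            continue
        prom = promoter.extract_promoter(gene, assembly, config.promoter_length)
        all_hits.extend(
            promoter.scan_elements(
                prom.sequence, strands=config.strands, gene_id=m.gene_id
            )
        )
    promoter.hits_to_bed_frame(all_hits).to_csv(
        outdir / "cis_hits.tsv", sep="\t", index=False
    )
    pres = promoter.presence_matrix(all_hits, [m.gene_id for m in confirmed])
    pres.to_csv(outdir / "cis_presence.tsv", sep="\t")
    report["promoters"] = {
        "n_hits": len(all_hits),
        "presence_counts": {
            el: int((pres[el] > 0).sum()) for el in pres.columns
        },
    }

    # --- glycosylation ---
    seq_rows = []
    conserved_counts = {"found": 0, "absent": 0, "anchor-missing": 0}
    for m in confirmed:
        for hit in glyco.scan_n_sequons(m.protein):
            seq_rows.append(
                {
                    "gene_id": m.gene_id,
                    "position": hit.position,
                    "triplet": hit.triplet,
                    "context": hit.context,
                }
            )
        call = glyco.conserved_sequon_between_anchors(m.protein, m.category)
        if call.status in conserved_counts:
            conserved_counts[call.status] += 1
    pd.DataFrame(seq_rows).to_csv(outdir / "sequons.tsv", sep="\t", index=False)
    report["glycosylation"] = {
        "n_sequons": len(seq_rows),
        "n_proteins_with_sequon": len({r["gene_id"] for r in seq_rows}),
        "category_B_conserved_site": conserved_counts,
    }

    # --- expression ---
    if inputs.expression and Path(inputs.expression).exists():
        matrix = expr.load_expression_tsv(inputs.expression)
        pair_tuples = [(p.gene_a, p.gene_b) for p in pairs]
        selected = expr.select_high_tissue(
            matrix, "XY", config.efp_threshold, pair_tuples
        )
        order, _, _ = expr.log2_heatmap_cluster(matrix)
        pd.Series(sorted(selected), name="gene_id").to_csv(
            outdir / "xylem_selection.tsv", sep="\t", index=False
        )
        report["expression"] = {
            "n_genes": len(matrix),
            "xylem_selected": sorted(selected),
            "cluster_order": list(order),
        }

    # --- phylogeny ---
    if inputs.alignment and Path(inputs.alignment).exists():
        aln = phylogeny.Alignment.from_fasta(inputs.alignment)
    else:
        fam_prot = {m.gene_id: m.protein for m in confirmed}
        aln = phylogeny.progressive_align(fam_prot) if len(fam_prot) >= 3 else None
    if aln is not None and len(aln.ids) >= 3:
        tree = phylogeny.bootstrap_support(
            aln, n_reps=config.bootstrap_reps, seed=config.seed
        )
        (outdir / "family_nj.nwk").write_text(tree.to_newick() + "\n")
        report["phylogeny"] = {
            "n_taxa": len(aln.ids),
            "n_bootstrap": config.bootstrap_reps,
            "newick": tree.to_newick(),
        }

    return report
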