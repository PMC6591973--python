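"""Exon/intron arrangements of the family genes.

Reports per-gene exon and intron lengths and the family-level counts the
characterization tracks: intronless genes, genes lacking an annotated
5'UTR, and the exon-number range per category.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from apfam.gene_structure import (
    family_structure_summary,
    reports_to_frame,
    structure_report,
)

_, genes, _, _, truth = common.load_dataset_files()
reports = [structure_report(g) for g in genes]
reports_to_frame(reports).to_csv(
    common.RESULTS / "structure.tsv", sep="\t", index=False
)
summary = family_structure_summary(reports, truth["categories"])

print(f"{summary['n_genes']} genes; exon counts span {summary['exon_count_range']}")
print(
    f"{summary['n_intronless']} intronless genes, "
    f"{summary['n_lacking_utr5']} lacking a 5'UTR"
)
for cat, info in summary["per_category"].items():
    print(f"  category {cat}: n={info['n']}, exons {info['exon_count_range']}")
print(f"wrote {common.RESULTS / 'structure.tsv'}")
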