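"""Scan 3-kb promoters for the ten SCW-related degenerate cis-elements.

Promoters are anchored at the transcription start (upstream of the 5'UTR)
and scanned on both strands with exact IUPAC set matching; the presence
matrix mirrors the per-gene element calls of the characterization.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from apfam.promoter import (
    extract_promoter,
    hits_to_bed_frame,
    presence_matrix,
    scan_elements,
)

assembly, genes, _, _, truth = common.load_dataset_files()
hits = []
planted_found = planted_total = 0
for g in genes:
    prom = extract_promoter(g, assembly)
    gene_hits = scan_elements(prom.sequence, gene_id=g.gene_id)
    hits.extend(gene_hits)
    found = {(h.element, h.start, h.strand) for h in gene_hits}
    for el, start, strand, _m in truth["promoter_hits"][g.gene_id]:
        planted_total += 1
        planted_found += (el, start, strand) in found

hits_to_bed_frame(hits).to_csv(
    common.RESULTS / "cis_hits.tsv", sep="\t", index=False
)
pres = presence_matrix(hits, [g.gene_id for g in genes])
pres.to_csv(common.RESULTS / "cis_presence.tsv", sep="\t")

print(f"{len(hits)} hits over {len(genes)} promoters")
print(f"planted instances recovered: {planted_found}/{planted_total}")
print("genes with each element:")
for el in pres.columns:
    print(f"  {el:6s} {(pres[el] > 0).sum()}")
print(f"wrote {common.RESULTS / 'cis_hits.tsv'} and cis_presence.tsv")
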