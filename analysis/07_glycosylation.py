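"""N-glycosylation sequon analysis per family protein.

Counts canonical N-X-[S/T] (X != P) acceptor sequons and, for nucellin-like
(category B) members, checks for the conserved site upstream of the GCGYDQ
anchor.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from apfam.glyco import conserved_sequon_between_anchors, scan_n_sequons

_, _, _, proteins, truth = common.load_dataset_files()
rows = []
for gid, prot in proteins.items():
    for h in scan_n_sequons(prot):
        rows.append(
            {"gene_id": gid, "position": h.position, "triplet": h.triplet,
             "context": h.context}
        )
df = pd.DataFrame(rows)
df.to_csv(common.RESULTS / "sequons.tsv", sep="\t", index=False)

with_sequon = df.gene_id.nunique()
b_genes = [g for g, c in truth["categories"].items() if c == "B"]
b_conserved = sum(
    conserved_sequon_between_anchors(proteins[g], "B").found for g in b_genes
)
print(f"{len(df)} sequons across {with_sequon}/{len(proteins)} proteins")
print(
    f"category-B proteins with the conserved site before GCGYDQ: "
    f"{b_conserved}/{len(b_genes)}"
)
print(f"wrote {common.RESULTS / 'sequons.tsv'}")
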