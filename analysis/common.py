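"""Shared paths and loaders for the numbered analysis scripts.

The pipeline runs on the package's stated synthetic world (67 genes, 7/6/54
category mix, tandem clusters of 3/2/6, ten segmental pairs) generated by
01_simulate.py; every later script reads its outputs from results/synthetic.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
# raw simulated inputs are large (multi-Mb FASTA); they live under scratch/
# and are regenerated by 01_simulate.py, only small tables go to results/
SYNTH = ROOT / "scratch" / "synthetic"
SEED = 1
RESULTS.mkdir(parents=True, exist_ok=True)


def load_dataset_files():
    from apfam.io_model import read_fasta, read_gff3, read_sequences

    if not (SYNTH / "genome.fa").exists():
        sys.exit("run analysis/01_simulate.py first")
    assembly = read_fasta(SYNTH / "genome.fa")
    genes = read_gff3(SYNTH / "annotation.gff3", assembly)
    cds = read_sequences(SYNTH / "cds.fa")
    proteins = read_sequences(SYNTH / "proteins.fa")
    truth = json.loads((SYNTH / "truth.json").read_text())
    return assembly, genes, cds, proteins, truth
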