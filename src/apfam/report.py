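"""Consolidated machine-readable report over the stage outputs.

Every field is traceable to a stage table; nothing is invented here.  A
light structural schema guards the JSON the pipeline emits.
"""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["consolidated_report", "validate_report", "write_report"]

# section -> required keys (sections themselves are optional: a report covers
# whatever stages ran)
_SCHEMA: dict[str, list[str]] = {
    "config": [],
    "identification": ["n_candidates", "n_confirmed", "category_counts"],
    "structure": ["n_genes", "n_intronless", "n_lacking_utr5"],
    "duplication": ["tandem_clusters", "n_pairs", "pairs"],
    "promoters": ["n_hits", "presence_counts"],
    "glycosylation": ["n_sequons", "n_proteins_with_sequon"],
    "expression": ["n_genes", "xylem_selected"],
    "phylogeny": ["n_taxa", "newick"],
}


def consolidated_report(stages: dict) -> dict:
    """Assemble and validate the consolidated report from stage sections."""
    if not stages:
        raise ValueError("report needs at least one stage output")
    report = {k: stages[k] for k in stages}
    # duplication list is always present once the stage ran, even when empty
    if "duplication" in report:
        report["duplication"].setdefault("pairs", [])
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    unknown = set(report) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown report sections: {sorted(unknown)}")
    for section, keys in _SCHEMA.items():
        if section not in report:
            continue
        missing = [k for k in keys if k not in report[section]]
        if missing:
            raise ValueError(f"report section {section!r} missing keys {missing}")


def write_report(report: dict, path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
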