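"""Synthetic genomes with planted aspartic-protease families and known truth.

Every stage of the pipeline is testable offline against data this module
generates: multi-chromosome assemblies with multi-exon gene models and UTRs,
proteins carrying the two D[TS]G catalytic motifs at realistic spacing,
category-A PSI-like cysteine-rich inserts, category-B QCDYE/GCGYDQ nucellin
motifs, tandem clusters inside the 50-kb rule, segmental duplicate pairs
diverged by a controlled number of synonymous/nonsynonymous substitutions
(with matching block intervals), promoters with planted degenerate-element
instances at known positions and strands, and tissue expression profiles
with planted xylem specificity.

Design notes: protein backgrounds are drawn from the 18-letter alphabet
without Cys and Asp, which makes the planted motifs the *only* catalytic
motifs, PSI inserts and nucellin sequences present — category recovery is
then exact by construction.  The defaults mirror the characterized family:
67 genes in a 7/6/54 A/B/C mix on 19 chromosomes with tandem clusters of
sizes 3, 2 and 6.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .duplication import CODON_TO_AA, STOPS, DuplicationBlockTable
from .io_model import (
    GeneModel,
    GenomeAssembly,
    GenomeInterval,
    reverse_complement,
    translate,
    write_fasta,
    write_gff3,
)
from .promoter import CIS_ELEMENT_CATALOG, IUPAC_SETS

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_family_genome",
    "evolve_codon_pair",
    "plant_cis_elements",
    "make_expression",
]

BACKGROUND_AA = "AEFGHIKLMNPQRSTVWY"  # 20 letters minus C and D (see module docstring)
TISSUES = ["ML", "YL", "RT", "FC", "MC", "XY"]

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_STOP_LIST = sorted(STOPS)


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 19
    chromosome_length_bp: int = 1_200_000
    n_family_genes: int = 67
    category_mix: tuple[int, int, int] = (7, 6, 54)  # A, B, C
    tandem_cluster_sizes: tuple[int, ...] = (3, 2, 6)
    # per segmental pair: (target synonymous, target nonsynonymous) substitutions
    segmental_pairs: tuple[tuple[int, int], ...] = (
        (30, 4), (25, 3), (20, 2), (35, 5), (15, 2),
        (40, 4), (10, 1), (28, 3), (22, 2), (18, 2),
    )
    elements_per_promoter: tuple[int, int] = (1, 3)
    promoter_length_bp: int = 3000
    utr5_absent_fraction: float = 0.25
    n_xylem_specific: int = 12
    xylem_archetype: float = 1500.0
    baseline_archetype: float = 50.0
    noise_sd: float = 50.0

    def __post_init__(self) -> None:
        if sum(self.category_mix) != self.n_family_genes:
            raise ValueError("category_mix must sum to n_family_genes")
        need = sum(self.tandem_cluster_sizes) + 2 * len(self.segmental_pairs)
        if need > self.n_family_genes:
            raise ValueError(
                "tandem clusters and segmental pairs need more genes than available"
            )
        if len(self.tandem_cluster_sizes) > self.n_chromosomes:
            raise ValueError("more tandem clusters than chromosomes")


@dataclass
class SyntheticTruth:
    categories: dict[str, str] = field(default_factory=dict)
    tandem_clusters: list[list[str]] = field(default_factory=list)
    segmental_pairs: list[dict] = field(default_factory=list)
    promoter_hits: dict[str, list[tuple]] = field(default_factory=dict)
    xylem_specific: list[str] = field(default_factory=list)
    xylem_selected_with_partners: list[str] = field(default_factory=list)
    expression_archetypes: dict[str, dict[str, float]] = field(default_factory=dict)
    tree_newick: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    cds: dict[str, str]
    proteins: dict[str, str]
    blocks: DuplicationBlockTable
    expression: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.assembly.sequences, outdir / "genome.fa")
        write_gff3(self.genes, outdir / "annotation.gff3")
        write_fasta(self.cds, outdir / "cds.fa")
        write_fasta(self.proteins, outdir / "proteins.fa")
        self.blocks.to_tsv(outdir / "blocks.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# Low-level generators
# ---------------------------------------------------------------------------


_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _bg_protein(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(list(BACKGROUND_AA), size=n))


def _bg_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _DNA_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _motif(rng: np.random.Generator) -> str:
    return "D" + ("T" if rng.random() < 0.5 else "S") + "G"


def _design_protein(rng: np.random.Generator, category: str) -> str:
    """A family protein of the given category, planted features only."""
    i_a = int(rng.integers(40, 81))  # 0-based index of the first catalytic Asp
    pre = "M" + _bg_protein(rng, i_a - 1)
    if category == "A":
        n_cys = int(rng.integers(6, 9))
        insert = list(_bg_protein(rng, 100))
        for pos in rng.choice(100, size=n_cys, replace=False):
            insert[pos] = "C"
        mid = _bg_protein(rng, 20) + "".join(insert) + _bg_protein(
            rng, int(rng.integers(40, 101))
        )
    elif category == "B":
        m1 = int(rng.integers(20, 60))
        m2 = int(rng.integers(20, 40))
        rest = int(rng.integers(20, 80))
        # a sequon 18 residues upstream of GCGYDQ (the conserved category-B site)
        mid = (
            _bg_protein(rng, m1)
            + "QCDYE"
            + _bg_protein(rng, m2)
            + "NAT"
            + _bg_protein(rng, 12)
            + "GCGYDQ"
            + _bg_protein(rng, rest)
        )
    else:
        mid = _bg_protein(rng, int(rng.integers(120, 331)))
    if not 97 <= len(mid) <= 347:  # keep Asp spacing within the [100, 350] rule
        mid = mid[:347] if len(mid) > 347 else mid + _bg_protein(rng, 97 - len(mid))
    tail = _bg_protein(rng, int(rng.integers(60, 121)))
    return pre + _motif(rng) + mid + _motif(rng) + tail


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [
        AA_TO_CODONS[aa][rng.integers(0, len(AA_TO_CODONS[aa]))] for aa in protein
    ]
    codons.append(_STOP_LIST[rng.integers(0, len(_STOP_LIST))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Codon-pair evolution
# ---------------------------------------------------------------------------


@dataclass
class MutationRecord:
    syn_positions: list[int]  # codon indices (0-based) of synonymous changes
    nonsyn_positions: list[int]

    @property
    def n_syn(self) -> int:
        return len(self.syn_positions)

    @property
    def n_nonsyn(self) -> int:
        return len(self.nonsyn_positions)


def _codon_neighbors(codon: str) -> list[tuple[str, bool]]:
    """(neighbor, is_synonymous) over stop-free single-nucleotide changes."""
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            out.append((alt, CODON_TO_AA[alt] == CODON_TO_AA[codon]))
    return out


def evolve_codon_pair(
    cds: str,
    n_syn: int,
    n_nonsyn: int,
    seed,
    forbidden_codons: Optional[set[int]] = None,
    allowed_nonsyn_aas: Optional[str] = None,
) -> tuple[str, MutationRecord]:
    """Apply exactly `n_syn` synonymous and `n_nonsyn` nonsynonymous
    single-nucleotide substitutions, each at a distinct codon.

    Synonymous changes preserve the amino acid, nonsynonymous ones change it,
    none may create a stop codon.  A trailing stop codon is left untouched.
    Raises when the request is infeasible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    has_stop = codons and codons[-1] in STOPS
    body = codons[:-1] if has_stop else list(codons)
    forbidden = forbidden_codons or set()

    syn_ok, nonsyn_ok = [], []
    for i, c in enumerate(body):
        if i in forbidden or c in STOPS:
            continue
        nbrs = _codon_neighbors(c)
        if any(s for _, s in nbrs):
            syn_ok.append(i)
        nonsyn_nbrs = [
            a
            for a, s in nbrs
            if not s
            and (allowed_nonsyn_aas is None or CODON_TO_AA[a] in allowed_nonsyn_aas)
        ]
        if nonsyn_nbrs:
            nonsyn_ok.append(i)

    chosen_syn = list(
        rng.choice(syn_ok, size=n_syn, replace=False) if n_syn else []
    ) if len(syn_ok) >= n_syn else None
    if chosen_syn is None:
        raise ValueError(
            f"infeasible: {n_syn} synonymous changes requested, "
            f"{len(syn_ok)} eligible codons"
        )
    remaining = [i for i in nonsyn_ok if i not in set(chosen_syn)]
    if len(remaining) < n_nonsyn:
        raise ValueError(
            f"infeasible: {n_nonsyn} nonsynonymous changes requested, "
            f"{len(remaining)} eligible codons"
        )
    chosen_nonsyn = list(
        rng.choice(remaining, size=n_nonsyn, replace=False) if n_nonsyn else []
    )

    for i in chosen_syn:
        options = [a for a, s in _codon_neighbors(body[i]) if s]
        body[i] = options[rng.integers(0, len(options))]
    for i in chosen_nonsyn:
        options = [
            a
            for a, s in _codon_neighbors(body[i])
            if not s
            and (allowed_nonsyn_aas is None or CODON_TO_AA[a] in allowed_nonsyn_aas)
        ]
        body[i] = options[rng.integers(0, len(options))]

    mutated = "".join(body) + (codons[-1] if has_stop else "")
    record = MutationRecord(
        sorted(int(i) for i in chosen_syn), sorted(int(i) for i in chosen_nonsyn)
    )
    return mutated, record


# ---------------------------------------------------------------------------
# Promoter planting
# ---------------------------------------------------------------------------


def plant_cis_elements(
    length_bp: int,
    instances: list[tuple[str, int, str]],
    seed,
    catalog: Optional[dict[str, str]] = None,
) -> tuple[str, list[tuple[str, int, str, str]]]:
    """Uniform-background promoter with planted element instances.

    `instances` are (element_name, 0-based offset, strand); each planted
    sequence is drawn uniformly from the consensus expansion (reverse-
    complemented for minus-strand instances).  Returns the sequence and truth
    hits as (element, 1-based start, strand, matched substring).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    catalog = catalog if catalog is not None else CIS_ELEMENT_CATALOG
    seq = list(_bg_dna(rng, length_bp))
    occupied: list[tuple[int, int]] = []
    truth = []
    for name, offset, strand in instances:
        consensus = catalog[name]
        end = offset + len(consensus)
        if offset < 0 or end > length_bp:
            raise ValueError(f"instance {name}@{offset} outside promoter")
        for s, e in occupied:
            if offset < e and s < end:
                raise ValueError(f"instance {name}@{offset} overlaps another instance")
        occupied.append((offset, end))
        concrete = "".join(
            sorted(IUPAC_SETS[c])[rng.integers(0, len(IUPAC_SETS[c]))]
            for c in consensus
        )
        planted = reverse_complement(concrete) if strand == "-" else concrete
        seq[offset:end] = planted
        truth.append((name, offset + 1, strand, planted))
    truth.sort(key=lambda t: t[1])
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def make_expression(
    genes: list[str],
    archetypes: dict[str, dict[str, float]],
    noise_sd: float,
    seed,
    tissues: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Archetype profile plus truncated Gaussian noise: max(0, mu + N(0, sd))."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tissues = tissues or TISSUES
    data = np.zeros((len(genes), len(tissues)))
    for i, g in enumerate(genes):
        prof = archetypes[g]
        mu = np.array([prof[t] for t in tissues], dtype=float)
        data[i] = np.maximum(0.0, mu + rng.normal(0.0, noise_sd, size=len(tissues)))
    return pd.DataFrame(data, index=genes, columns=tissues)


# ---------------------------------------------------------------------------
# Full-genome simulation
# ---------------------------------------------------------------------------


def _gene_layout(
    rng: np.random.Generator, cds_seq: str, with_utr5: bool
) -> tuple[str, dict]:
    """Coding-strand gene sequence plus relative (coding-strand) intervals."""
    n_exons = int(rng.integers(1, 13))
    L = len(cds_seq)
    bounds = [0]
    for i in range(1, n_exons):
        b = round(L * i / n_exons) + int(rng.integers(-5, 6))
        bounds.append(min(max(b, bounds[-1] + 20), L - 20 * (n_exons - i)))
    bounds.append(L)
    cds_parts = [cds_seq[a:b] for a, b in zip(bounds, bounds[1:])]
    utr5 = _bg_dna(rng, int(rng.integers(80, 200))) if with_utr5 else ""
    utr3 = _bg_dna(rng, int(rng.integers(100, 250)))
    introns = [_bg_dna(rng, int(rng.integers(150, 800))) for _ in range(n_exons - 1)]

    seq_parts, exons, cds_iv, utr5_iv, utr3_iv = [], [], [], [], []
    pos = 0
    for i, part in enumerate(cds_parts):
        exon_start = pos
        if i == 0 and utr5:
            seq_parts.append(utr5)
            utr5_iv.append((pos, pos + len(utr5)))
            pos += len(utr5)
        seq_parts.append(part)
        cds_iv.append((pos, pos + len(part)))
        pos += len(part)
        if i == n_exons - 1 and utr3:
            seq_parts.append(utr3)
            utr3_iv.append((pos, pos + len(utr3)))
            pos += len(utr3)
        exons.append((exon_start, pos))
        if i < n_exons - 1:
            seq_parts.append(introns[i])
            pos += len(introns[i])
    return "".join(seq_parts), {
        "exons": exons,
        "cds": cds_iv,
        "utr5": utr5_iv,
        "utr3": utr3_iv,
    }


def _rel_to_genomic(rel: tuple[int, int], g0: int, span: int, strand: str, chrom: str):
    s, e = rel
    if strand == "+":
        return GenomeInterval(chrom, g0 + s, g0 + e, strand)
    return GenomeInterval(chrom, g0 + span - e, g0 + span - s, strand)


def simulate_family_genome(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset (reproducible under config.seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_family_genes
    gene_ids = [f"synAP{i + 1:03d}" for i in range(n)]

    # --- roles: segmental pairs (same category both sides), tandem clusters ---
    remaining = {"A": config.category_mix[0], "B": config.category_mix[1],
                 "C": config.category_mix[2]}
    pair_categories = []
    for _ in config.segmental_pairs:
        cat = max(remaining, key=lambda c: (remaining[c], c))
        if remaining[cat] < 2:
            raise ValueError("category_mix cannot cover the segmental pairs")
        remaining[cat] -= 2
        pair_categories.append(cat)
    # tandem duplicates are recent copies, so a cluster shares one category
    cluster_categories = []
    for size in config.tandem_cluster_sizes:
        cat = max(remaining, key=lambda c: (remaining[c], c))
        if remaining[cat] < size:
            raise ValueError("category_mix cannot cover the tandem clusters")
        remaining[cat] -= size
        cluster_categories.append(cat)
    singles = [c for c in "ABC" for _ in range(remaining[c])]
    singles = [singles[i] for i in rng.permutation(len(singles))]

    slots = iter(gene_ids)
    pair_members: list[tuple[str, str]] = [
        (next(slots), next(slots)) for _ in config.segmental_pairs
    ]
    rest = list(slots)
    cluster_ids: list[list[str]] = []
    cursor = 0
    for size in config.tandem_cluster_sizes:
        cluster_ids.append(rest[cursor : cursor + size])
        cursor += size
    single_ids = rest[cursor:]

    categories: dict[str, str] = {}
    for (ga, gb), cat in zip(pair_members, pair_categories):
        categories[ga] = categories[gb] = cat
    for cluster, cat in zip(cluster_ids, cluster_categories):
        for gid in cluster:
            categories[gid] = cat
    for gid, cat in zip(single_ids, singles):
        categories[gid] = cat

    # --- sequences ---
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    truth = SyntheticTruth(categories=dict(categories))

    def _protected_codons(prot: str) -> set[int]:
        """Codons whose nonsynonymous change could break a planted feature:
        the start, every Cys/Asp-bearing motif region, every sequon."""
        protected = {0} | {i for i, aa in enumerate(prot) if aa in "CD"}
        protected |= {i + d for i in list(protected) for d in (1, 2)}
        for i in range(len(prot) - 2):
            if prot[i] == "N" and prot[i + 1] != "P" and prot[i + 2] in "ST":
                protected |= {i, i + 1, i + 2}
        return protected

    def _derive(gid_from: str, n_syn: int, n_nonsyn: int):
        mutated, record = evolve_codon_pair(
            cds[gid_from],
            n_syn,
            n_nonsyn,
            rng,
            forbidden_codons=_protected_codons(proteins[gid_from]),
            allowed_nonsyn_aas=BACKGROUND_AA,
        )
        return mutated, record

    for gid in single_ids:
        proteins[gid] = _design_protein(rng, categories[gid])
        cds[gid] = _reverse_translate(rng, proteins[gid])

    # tandem clusters: recent copies of a founder, modestly diverged
    for cluster in cluster_ids:
        founder = cluster[0]
        proteins[founder] = _design_protein(rng, categories[founder])
        cds[founder] = _reverse_translate(rng, proteins[founder])
        for gid in cluster[1:]:
            mutated, _rec = _derive(
                founder, int(rng.integers(8, 26)), int(rng.integers(1, 5))
            )
            cds[gid] = mutated
            proteins[gid] = translate(mutated).protein

    for (ga, gb), (n_syn, n_nonsyn) in zip(pair_members, config.segmental_pairs):
        proteins[ga] = _design_protein(rng, categories[ga])
        cds[ga] = _reverse_translate(rng, proteins[ga])
        mutated, record = _derive(ga, n_syn, n_nonsyn)
        cds[gb] = mutated
        proteins[gb] = translate(mutated).protein
        truth.segmental_pairs.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "n_syn": record.n_syn,
                "n_nonsyn": record.n_nonsyn,
                "syn_positions": record.syn_positions,
                "nonsyn_positions": record.nonsyn_positions,
            }
        )
    truth.tandem_clusters = [list(c) for c in cluster_ids]
    cherries = ",".join(f"({a},{b})" for a, b in pair_members)
    clades = ",".join(
        "(" + ",".join(c) + ")" for c in cluster_ids if len(c) > 1
    )
    others = ",".join(single_ids)
    parts = ",".join(p for p in (cherries, clades, others) if p)
    truth.tree_newick = f"({parts});"

    # --- chromosome layout ---
    chrom_names = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    placements: dict[str, list[tuple[str, bool]]] = {c: [] for c in chrom_names}
    for ci, cluster in enumerate(cluster_ids):
        placements[chrom_names[ci]].extend(
            (gid, k > 0) for k, gid in enumerate(cluster)
        )
    loose = [g for g in gene_ids if not any(g in c for c in cluster_ids)]
    for k, gid in enumerate(loose):
        placements[chrom_names[k % config.n_chromosomes]].append((gid, False))

    pl = config.promoter_length_bp
    chrom_arrays: dict[str, np.ndarray] = {}
    gene_models: list[GeneModel] = []
    gene_iv: dict[str, GenomeInterval] = {}
    for chrom in chrom_names:
        arr = _DNA_BYTES[
            rng.integers(0, 4, size=config.chromosome_length_bp)
        ].copy()
        pos = pl + int(rng.integers(200, 2000))
        for gid, is_follower in placements[chrom]:
            strand = "+" if rng.random() < 0.5 else "-"
            with_utr5 = rng.random() >= config.utr5_absent_fraction
            coding_seq, rel = _gene_layout(rng, cds[gid], with_utr5)
            span = len(coding_seq)
            genomic_seq = (
                coding_seq if strand == "+" else reverse_complement(coding_seq)
            )
            g0 = pos
            if g0 + span + pl > config.chromosome_length_bp:
                raise ValueError(
                    f"config infeasible: genes do not fit on {chrom} "
                    f"(length {config.chromosome_length_bp})"
                )
            arr[g0 : g0 + span] = np.frombuffer(
                genomic_seq.encode("ascii"), dtype=np.uint8
            )
            # promoter with planted elements, on the coding strand
            k = int(
                rng.integers(
                    config.elements_per_promoter[0],
                    config.elements_per_promoter[1] + 1,
                )
            )
            names = list(CIS_ELEMENT_CATALOG)
            instances = []
            taken: list[tuple[int, int]] = []
            for _ in range(k):
                name = names[rng.integers(0, len(names))]
                length = len(CIS_ELEMENT_CATALOG[name])
                for _try in range(50):
                    off = int(rng.integers(0, pl - length))
                    if all(off >= e or off + length <= s for s, e in taken):
                        taken.append((off, off + length))
                        instances.append(
                            (name, off, "+" if rng.random() < 0.5 else "-")
                        )
                        break
            prom_seq, prom_truth = plant_cis_elements(pl, instances, rng)
            if strand == "+":
                arr[g0 - pl : g0] = np.frombuffer(
                    prom_seq.encode("ascii"), dtype=np.uint8
                )
            else:
                arr[g0 + span : g0 + span + pl] = np.frombuffer(
                    reverse_complement(prom_seq).encode("ascii"), dtype=np.uint8
                )
            truth.promoter_hits[gid] = prom_truth

            iv = GenomeInterval(chrom, g0, g0 + span, strand)
            gene_iv[gid] = iv
            gene_models.append(
                GeneModel(
                    gene_id=gid,
                    interval=iv,
                    exons=[
                        _rel_to_genomic(r, g0, span, strand, chrom)
                        for r in rel["exons"]
                    ],
                    cds=[
                        _rel_to_genomic(r, g0, span, strand, chrom)
                        for r in rel["cds"]
                    ],
                    utr5=[
                        _rel_to_genomic(r, g0, span, strand, chrom)
                        for r in rel["utr5"]
                    ],
                    utr3=[
                        _rel_to_genomic(r, g0, span, strand, chrom)
                        for r in rel["utr3"]
                    ],
                )
            )
            gap = (
                int(rng.integers(20_000, 45_001))
                if _next_is_follower(placements[chrom], gid)
                else int(rng.integers(60_000, 120_001))
            )
            pos = g0 + span + pl + gap
        chrom_arrays[chrom] = arr

    assembly = GenomeAssembly(
        {c: chrom_arrays[c].tobytes().decode("ascii") for c in chrom_names}
    )
    gene_models.sort(key=lambda g: (g.interval.chrom, g.interval.start))

    # --- duplication blocks around the segmental pairs ---
    rows = []
    for bi, (ga, gb) in enumerate(pair_members):
        iva, ivb = gene_iv[ga], gene_iv[gb]
        pad_a = int(rng.integers(2_000, 10_001))
        pad_b = int(rng.integers(2_000, 10_001))
        rows.append(
            (
                f"blk{bi + 1:03d}",
                GenomeInterval(
                    iva.chrom,
                    max(0, iva.start - pad_a),
                    min(assembly.length(iva.chrom), iva.end + pad_a),
                ),
                GenomeInterval(
                    ivb.chrom,
                    max(0, ivb.start - pad_b),
                    min(assembly.length(ivb.chrom), ivb.end + pad_b),
                ),
            )
        )
    blocks = DuplicationBlockTable(rows)

    # --- expression ---
    xylem = [
        gene_ids[i]
        for i in sorted(
            rng.choice(n, size=config.n_xylem_specific, replace=False)
        )
    ]
    truth.xylem_specific = list(xylem)
    # "corresponding replication genes": close over segmental partners AND
    # tandem-cluster co-members, mirroring the selection rule downstream
    partners: dict[str, set[str]] = {}
    for ga, gb in pair_members:
        partners.setdefault(ga, set()).add(gb)
        partners.setdefault(gb, set()).add(ga)
    for cluster in cluster_ids:
        for g in cluster:
            partners.setdefault(g, set()).update(set(cluster) - {g})
    closed = set(xylem)
    frontier = list(xylem)
    while frontier:
        g = frontier.pop()
        for p in partners.get(g, ()):
            if p not in closed:
                closed.add(p)
                frontier.append(p)
    truth.xylem_selected_with_partners = sorted(closed)
    archetypes: dict[str, dict[str, float]] = {}
    for gid in gene_ids:
        if gid in xylem:
            prof = {t: config.baseline_archetype for t in TISSUES}
            prof["XY"] = config.xylem_archetype
        else:
            prof = {t: float(rng.uniform(100, 800)) for t in TISSUES}
            prof["XY"] = float(rng.uniform(100, 700))
        archetypes[gid] = prof
    truth.expression_archetypes = archetypes
    expression = make_expression(gene_ids, archetypes, config.noise_sd, rng)

    return SyntheticDataset(
        config=config,
        assembly=assembly,
        genes=gene_models,
        cds=cds,
        proteins=proteins,
        blocks=blocks,
        expression=expression,
        truth=truth,
    )


def _next_is_follower(placement: list[tuple[str, bool]], gid: str) -> bool:
    for k, (g, _) in enumerate(placement):
        if g == gid:
            return k + 1 < len(placement) and placement[k + 1][1]
    return False
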