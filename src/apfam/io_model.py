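"""Genome assemblies, gene models and the standard-format I/O every stage consumes.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based inclusive)
is converted at the boundary.  Assemblies are plain in-memory dictionaries of
uppercase nucleotide strings restricted to {A, C, G, T, N}.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDES = frozenset("ACGTN")

__all__ = [
    "GenomeAssembly",
    "GenomeInterval",
    "GeneModel",
    "Translation",
    "read_fasta",
    "read_sequences",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "extract_cds",
    "translate",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomeInterval") -> int:
        """Distance between nearest boundaries; 0 if the intervals touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


class GenomeAssembly:
    """Chromosome name -> uppercase nucleotide sequence."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("assembly has no sequences")
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name}")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise ValueError(
                    f"sequence {name} contains non-ACGTN characters: {sorted(bad)}"
                )
        self.sequences = dict(sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def names(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, iv: GenomeInterval) -> str:
        """Sequence of `iv` on its own strand (minus intervals reverse-complemented)."""
        seq = self.sequences.get(iv.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {iv.chrom}")
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {len(seq)}"
            )
        sub = seq[iv.start : iv.end]
        return reverse_complement(sub) if iv.strand == "-" else sub


@dataclass
class GeneModel:
    """One annotated gene with a single (primary) transcript model."""

    gene_id: str
    interval: GenomeInterval
    exons: list[GenomeInterval] = field(default_factory=list)
    cds: list[GenomeInterval] = field(default_factory=list)
    utr5: list[GenomeInterval] = field(default_factory=list)
    utr3: list[GenomeInterval] = field(default_factory=list)
    primary_rule: str = "only"  # how the transcript was selected: only | dot1 | longest_cds

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds = sorted(self.cds, key=lambda c: c.start)
        self.utr5 = sorted(self.utr5, key=lambda u: u.start)
        self.utr3 = sorted(self.utr3, key=lambda u: u.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                if self.exons:
                    raise ValueError(
                        f"{self.gene_id}: CDS segment {c.start}-{c.end} outside exons"
                    )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path) -> dict[str, str]:
    """Raw FASTA records (uppercased), keyed by the first header token."""
    out: dict[str, str] = {}
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA ID: {rec.id}")
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_fasta(path, ambiguous: str = "reject") -> GenomeAssembly:
    """Load a nucleotide FASTA as a :class:`GenomeAssembly`.

    ambiguous: 'reject' errors on characters outside ACGTN; 'map-n' converts
    them (IUPAC ambiguity codes etc.) to N.
    """
    seqs = read_sequences(path)
    if ambiguous == "map-n":
        seqs = {
            name: "".join(c if c in NUCLEOTIDES else "N" for c in seq)
            for name, seq in seqs.items()
        }
    return GenomeAssembly(seqs)


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr"}


def _iv_from_feature(feat, strand: str) -> GenomeInterval:
    # GFF3 is 1-based inclusive
    return GenomeInterval(feat.seqid, feat.start - 1, feat.end, strand)


def _select_primary(mrnas) -> tuple[object, str]:
    if len(mrnas) == 1:
        return mrnas[0], "only"
    for m in mrnas:
        if m.id.endswith(".1"):
            return m, "dot1"
    return max(mrnas, key=lambda m: m._cds_len), "longest_cds"


def read_gff3(path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Parse a GFF3 annotation into one :class:`GeneModel` per gene.

    The primary transcript is the mRNA whose ID ends ``.1``, else the one with
    the longest CDS; the rule used is recorded on the model.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in assembly:
            raise ValueError(f"gene {gene.id} on unknown chromosome {gene.seqid}")
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        for m in mrnas:
            m._cds_len = sum(
                c.end - c.start + 1 for c in db.children(m, featuretype="CDS")
            )
        mrna, rule = _select_primary(mrnas)
        strand = gene.strand if gene.strand in ("+", "-") else "+"
        gene_iv = _iv_from_feature(gene, strand)
        exons = [
            _iv_from_feature(f, strand) for f in db.children(mrna, featuretype="exon")
        ]
        cds = [
            _iv_from_feature(f, strand) for f in db.children(mrna, featuretype="CDS")
        ]
        utr5, utr3 = [], []
        for f in db.children(mrna):
            if f.featuretype in _UTR5_TYPES:
                utr5.append(_iv_from_feature(f, strand))
            elif f.featuretype in _UTR3_TYPES:
                utr3.append(_iv_from_feature(f, strand))
        for c in cds:
            if c.start < gene_iv.start or c.end > gene_iv.end:
                raise ValueError(
                    f"gene {gene.id}: CDS segment {c.start}-{c.end} outside gene span"
                )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                interval=gene_iv,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                primary_rule=rule,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Serialize gene models (one mRNA per gene, ID = <gene_id>.1)."""

    def line(chrom, ftype, iv, ID, parent=None):
        attrs = f"ID={ID}" + (f";Parent={parent}" if parent else "")
        return (
            f"{chrom}\t.\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            mid = f"{g.gene_id}.1"
            fh.write(line(g.interval.chrom, "gene", g.interval, g.gene_id) + "\n")
            fh.write(
                line(g.interval.chrom, "mRNA", g.interval, mid, g.gene_id) + "\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(line(e.chrom, "exon", e, f"{mid}.exon{i}", mid) + "\n")
            for i, c in enumerate(g.cds, 1):
                fh.write(line(c.chrom, "CDS", c, f"{mid}.cds{i}", mid) + "\n")
            for i, u in enumerate(g.utr5, 1):
                fh.write(
                    line(u.chrom, "five_prime_UTR", u, f"{mid}.utr5.{i}", mid) + "\n"
                )
            for i, u in enumerate(g.utr3, 1):
                fh.write(
                    line(u.chrom, "three_prime_UTR", u, f"{mid}.utr3.{i}", mid) + "\n"
                )


# ---------------------------------------------------------------------------
# CDS extraction and translation
# ---------------------------------------------------------------------------


def extract_cds(gene: GeneModel, assembly: GenomeAssembly) -> str:
    """Spliced coding sequence in transcription order (minus strand rev-comped)."""
    if not gene.cds:
        raise ValueError(f"{gene.gene_id}: no CDS segments")
    parts = []
    for c in gene.cds:  # sorted by genomic start
        if c.end > assembly.length(c.chrom):
            raise ValueError(
                f"{gene.gene_id}: CDS segment exceeds chromosome {c.chrom}"
            )
        parts.append(assembly[c.chrom][c.start : c.end])
    plus = "".join(parts)
    return reverse_complement(plus) if gene.strand == "-" else plus


class Translation(NamedTuple):
    protein: str
    stopped: bool  # a stop codon was reached
    internal_stop: bool  # the stop was not the final codon

    def __str__(self) -> str:  # convenience for code treating it as a sequence
        return self.protein


def translate(cds: str) -> Translation:
    """Standard-code translation, terminating at the first stop codon."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    n_codons = len(cds) // 3
    aa = str(Seq(cds).translate())
    stop_at = aa.find("*")
    if stop_at == -1:
        return Translation(aa, False, False)
    return Translation(aa[:stop_at], True, stop_at < n_codons - 1)
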