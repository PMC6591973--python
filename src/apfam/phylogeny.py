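"""Distance-based neighbor-joining phylogenies with bootstrap support.

The guide multiple alignment is normally supplied externally (aligned FASTA);
a simple center-star progressive aligner is included as an approximate
fallback.  Distances are Poisson-corrected protein distances with pairwise
deletion by default (p-distance selectable), trees are built with the
Saitou-Nei agglomeration using a deterministic lowest-index tie-break, and
bootstrap support is the percentage of column-resampled replicate trees
containing each internal bipartition of the full-data tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PhyloTree",
    "pairwise_align",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "progressive_align",
]


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, cols: np.ndarray) -> "Alignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(list(self.ids), rows)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from .io_model import read_sequences

        seqs = read_sequences(path)
        return cls(list(seqs), list(seqs.values()))

    def to_fasta(self, path) -> None:
        from .io_model import write_fasta

        write_fasta(dict(zip(self.ids, self.rows)), path)


# ---------------------------------------------------------------------------
# Pairwise alignment (Biopython aligner behind the module surface)
# ---------------------------------------------------------------------------


@dataclass
class PairwiseResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: int  # identical pairs / alignment columns, nearest integer


def pairwise_align(
    a: str,
    b: str,
    matrix: Optional[str] = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    match: Optional[float] = None,
    mismatch: Optional[float] = None,
) -> PairwiseResult:
    """Optimal global alignment (end gaps penalized) and percent identity.

    Pass ``match``/``mismatch`` for unit-style scoring instead of a named
    substitution matrix.
    """
    if not a or not b:
        other = a or b
        n = len(other)
        score = 0.0 if n == 0 else gap_open + (n - 1) * gap_extend
        return PairwiseResult(a or "-" * n, b or "-" * n, score, 0)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if match is not None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch if mismatch is not None else -match
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    pid = round(100.0 * ident / len(ra)) if ra else 0
    return PairwiseResult(ra, rb, float(aln.score), pid)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    flags: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise-deletion p or Poisson-corrected (-ln(1-p)) protein distances."""
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(aln.ids)
    M = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8).reshape(
        n, aln.ncol
    )
    valid = M != ord("-")
    d = np.zeros((n, n))
    flags = []
    for i in range(n):
        comp = valid[i] & valid[i + 1 :]
        compared = comp.sum(axis=1).astype(float)
        diffs = ((M[i] != M[i + 1 :]) & comp).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = diffs / compared
        for k, j in enumerate(range(i + 1, n)):
            if compared[k] == 0:
                dij = np.nan
                flags.append((aln.ids[i], aln.ids[j], "no-overlap"))
            elif model == "p":
                dij = p[k]
            elif p[k] >= 1.0:
                dij = np.nan
                flags.append((aln.ids[i], aln.ids[j], "poisson-saturated"))
            else:
                dij = -math.log(1.0 - p[k])
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(aln.ids), d, flags)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class TreeNode:
    __slots__ = ("name", "children", "support")

    def __init__(self, name: Optional[str] = None):
        self.name = name
        self.children: list[tuple["TreeNode", float]] = []  # (child, branch length)
        self.support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode  # trifurcating root representing the unrooted tree
    ids: list[str]
    negative_clamped: bool = False

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length metric between all leaf pairs."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def walk(node: TreeNode) -> None:
            nid = id(node)
            adj.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for child, length in node.children:
                cid = id(child)
                adj.setdefault(cid, []).append((nid, length))
                adj[nid].append((cid, length))
                walk(child)

        walk(self.root)
        index = {name: k for k, name in enumerate(self.ids)}
        d = np.zeros((len(self.ids), len(self.ids)))
        for nid, name in names.items():
            dist = {nid: 0.0}
            stack = [nid]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            i = index[name]
            for mid, mname in names.items():
                d[i, index[mname]] = dist[mid]
        return DistanceMatrix(list(self.ids), d)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized to the side lacking ids[0]."""
        all_leaves = set(self.ids)
        ref = self.ids[0]
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> set:
            if node.is_leaf:
                return {node.name}
            below = set()
            for c, _ in node.children:
                below |= walk(c)
            if node is not self.root:
                side = below if ref not in below else all_leaves - below
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(frozenset(side))
            return below

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode, length: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6g}"

        return fmt(self.root, None) + ";"


def nj_tree(dm: DistanceMatrix, clamp_negative: bool = True) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken toward the lowest index pair (indices
    in current-node creation order), making the output deterministic.  For an
    additive input matrix the tree's path-length metric reproduces the input.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains undefined entries")
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.ids]
    D = dm.d.copy()
    active = list(range(n))
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if clamp_negative and x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        Da = D[np.ix_(idx, idx)]
        r = Da.sum(axis=1)
        Q = (m - 2) * Da - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        # np.argmin scans upper-triangle pairs in row-major order, so ties
        # resolve to the lowest index pair (indices in node-creation order)
        k = int(np.argmin(Q[iu]))
        ai, aj = int(iu[0][k]), int(iu[1][k])
        i, j = active[ai], active[aj]
        li = 0.5 * Da[ai, aj] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = Da[ai, aj] - li
        parent = TreeNode()
        parent.children = [(nodes[i], clamp(li)), (nodes[j], clamp(lj))]
        # new distances
        k_new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [k_new]

    i, j, k = active
    root = TreeNode()
    root.children = [
        (nodes[i], clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))),
        (nodes[j], clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))),
        (nodes[k], clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))),
    ]
    return PhyloTree(root, list(dm.ids), negative_clamped=clamped)


def bootstrap_support(
    aln: Alignment, n_reps: int = 1000, seed: int = 0, model: str = "poisson"
) -> PhyloTree:
    """NJ tree with per-internal-edge bootstrap supports (0-100).

    Columns are resampled with replacement; support is the percentage of
    replicate trees containing each internal bipartition of the full tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(aln, model))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, aln.ncol, size=aln.ncol)
        rep = aln.resample_columns(cols)
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:  # saturated / degenerate resample
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    all_leaves = set(tree.ids)
    ref = tree.ids[0]

    def annotate(node: TreeNode) -> set:
        if node.is_leaf:
            return {node.name}
        below = set()
        for c, _ in node.children:
            below |= annotate(c)
        if node is not tree.root:
            side = below if ref not in below else all_leaves - below
            node.support = supports.get(frozenset(side))
        return below

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Approximate progressive (center-star) aligner
# ---------------------------------------------------------------------------


def _kmer_profile(seq: str, k: int = 3) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def _kmer_distance(pa: dict, pb: dict) -> float:
    shared = sum(min(c, pb.get(kmer, 0)) for kmer, c in pa.items())
    total = max(1, min(sum(pa.values()), sum(pb.values())))
    return 1.0 - shared / total


def progressive_align(seqs: dict[str, str], **align_kwargs) -> Alignment:
    """Approximate center-star MSA: every sequence aligned to the most central one.

    Intended only as a fallback; supply an externally computed alignment for
    real-data phylogenies.
    """
    ids = list(seqs)
    if len(ids) == 1:
        return Alignment(ids, [seqs[ids[0]]])
    profs = {i: _kmer_profile(seqs[i]) for i in ids}
    center = min(
        ids, key=lambda i: sum(_kmer_distance(profs[i], profs[j]) for j in ids)
    )
    master = seqs[center]  # center row with accumulated gaps
    rows: dict[str, str] = {center: master}
    for other in ids:
        if other == center:
            continue
        pr = pairwise_align(seqs[center], seqs[other], **align_kwargs)
        # merge (pr.aligned_a, pr.aligned_b) into the master ("once a gap, always a gap")
        new_master, new_row = [], []
        patched: dict[str, list[str]] = {i: [] for i in rows if i != center}
        mi = ai = 0
        while mi < len(master) or ai < len(pr.aligned_a):
            mc = master[mi] if mi < len(master) else None
            ac = pr.aligned_a[ai] if ai < len(pr.aligned_a) else None
            if mc == "-" and ac != mc:
                new_master.append("-")
                new_row.append("-")
                for i in patched:
                    patched[i].append(rows[i][mi])
                mi += 1
            elif ac == "-" and (mc != "-" or mc is None):
                new_master.append("-")
                new_row.append(pr.aligned_b[ai])
                for i in patched:
                    patched[i].append("-")
                ai += 1
            else:  # residues agree (same underlying center residue) or both gaps
                new_master.append(mc if mc is not None else "-")
                new_row.append(pr.aligned_b[ai] if ac is not None else "-")
                for i in patched:
                    patched[i].append(rows[i][mi] if mi < len(master) else "-")
                mi += 1
                ai += 1
        master = "".join(new_master)
        for i in patched:
            rows[i] = "".join(patched[i])
        rows[center] = master
        rows[other] = "".join(new_row)
    return Alignment(ids, [rows[i] for i in ids])
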