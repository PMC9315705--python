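"""Shared-gene supermatrix construction and bootstrap neighbor-joining.

Single-copy protein-coding genes present in every taxon are extracted from
annotations (spliced on the coding strand), aligned per gene, and
concatenated into a supermatrix with recorded partitions.  Tree inference is
Saitou-Nei neighbor joining on p- or JC69 distances with pairwise deletion
of gap/N sites, plus nonparametric bootstrap by column resampling; for
plastomes of one species complex the phylogenetic signal is a modest number
of shared SNPs, which distance methods recover exactly, so NJ serves as the
inference engine with ML deliberately out of scope.

Determinism: Q-matrix ties break on the smallest (i, j) pair index and the
bootstrap is driven by a caller-supplied seed, so identical inputs give
bit-identical newick output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import banded_align
from .io_formats import Plastome, revcomp

__all__ = [
    "Supermatrix",
    "TreeNode",
    "PhyloTree",
    "extract_shared_genes",
    "build_supermatrix",
    "distance_matrix",
    "neighbor_joining",
    "nj_tree",
]


# ---------------------------------------------------------------------------
# Gene extraction and supermatrix


def _splice(genome: Plastome, feat) -> str:
    parts = sorted(feat.parts)
    seq = "".join(genome.sequence[s:e] for s, e in parts)
    return revcomp(seq) if feat.strand == "-" else seq


def extract_shared_genes(genomes: list[Plastome]) -> dict[str, dict[str, str]]:
    """Spliced CDS of single-copy protein-coding genes shared by all taxa.

    Genes duplicated by the IR are excluded; a gene missing (or multi-copy)
    in any taxon is dropped from the shared set.
    """
    per_taxon: dict[str, dict[str, list]] = {}
    for g in genomes:
        if not g.annotations:
            raise ValueError(f"taxon {g.id} lacks annotations")
        genes: dict[str, list] = {}
        for feat in g.annotations:
            if feat.kind != "CDS" or feat.copy_tag != "single":
                continue
            genes.setdefault(feat.name, []).append(feat)
        per_taxon[g.id] = genes
    shared = None
    for genes in per_taxon.values():
        names = {n for n, feats in genes.items() if len(feats) == 1}
        shared = names if shared is None else shared & names
    out: dict[str, dict[str, str]] = {}
    by_id = {g.id: g for g in genomes}
    for name in sorted(shared or ()):
        out[name] = {
            tid: _splice(by_id[tid], per_taxon[tid][name][0]) for tid in per_taxon
        }
    return out


@dataclass
class Supermatrix:
    """Concatenated per-gene alignments with partition boundaries."""

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) half-open

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("unequal supermatrix row lengths")

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows])


def _align_gene(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star alignment of one gene's near-identical sequences."""
    taxa = sorted(seqs)
    center = taxa[0]
    ref = seqs[center]
    subs: dict[str, list[str]] = {}
    ins_maps: dict[str, dict[int, str]] = {}
    from .comparative import _pairwise_to_events

    band = max(60, max(abs(len(seqs[t]) - len(ref)) for t in taxa) + 30)
    for t in taxa:
        if t == center:
            continue
        ra, sa, _ = banded_align(ref, seqs[t], band=band)
        subs[t], ins_maps[t] = _pairwise_to_events(ra, sa)
    n = len(ref)
    ins_len = [0] * (n + 1)
    for m in ins_maps.values():
        for r, s in m.items():
            ins_len[r] = max(ins_len[r], len(s))
    aligned: dict[str, str] = {}
    for t in taxa:
        out: list[str] = []
        for r in range(n + 1):
            if t == center:
                out.append("-" * ins_len[r])
                if r < n:
                    out.append(ref[r])
            else:
                s = ins_maps[t].get(r, "")
                out.append(s + "-" * (ins_len[r] - len(s)))
                if r < n:
                    out.append(subs[t][r])
        aligned[t] = "".join(out)
    return aligned


def build_supermatrix(gene_seqs: dict[str, dict[str, str]]) -> Supermatrix:
    """Concatenate per-gene alignments; taxa ordered canonically (sorted)."""
    if not gene_seqs:
        raise ValueError("no shared genes to concatenate")
    taxa = sorted(next(iter(gene_seqs.values())))
    for name, seqs in gene_seqs.items():
        if sorted(seqs) != taxa:
            raise ValueError(f"gene {name} missing some taxa")
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for name in sorted(gene_seqs):
        aligned = _align_gene(gene_seqs[name])
        glen = len(next(iter(aligned.values())))
        parts.append((name, offset, offset + glen))
        offset += glen
        for t in taxa:
            chunks[t].append(aligned[t])
    return Supermatrix(taxa=taxa, rows=["".join(chunks[t]) for t in taxa], partitions=parts)


def supermatrix_from_alignment(aln, reference: Plastome,
                               taxa: list[str] | None = None) -> Supermatrix:
    """Supermatrix of single-copy CDS genes read off a whole-genome alignment.

    Gene columns are located through the reference annotation's coordinates;
    rows are already aligned, so no per-gene realignment is needed.  Sample
    insertions inside genes are dropped (reference columns only), which for
    near-identical genomes costs at most a few sites.
    """
    if not reference.annotations:
        raise ValueError(f"reference {reference.id} lacks annotations")
    col_of_ref = np.full(int(aln.ref_coords.max()) + 1, -1, dtype=np.int64)
    for c, r in enumerate(aln.ref_coords):
        if r >= 0:
            col_of_ref[r] = c
    taxa = sorted(taxa) if taxa is not None else sorted(aln.ids)
    rows_src = {t: aln.row(t) for t in taxa}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for feat in sorted(reference.annotations, key=lambda f: f.start):
        if feat.kind != "CDS" or feat.copy_tag != "single":
            continue
        cols: list[int] = []
        for s, e in sorted(feat.parts):
            cols.extend(int(col_of_ref[r]) for r in range(s, e))
        glen = len(cols)
        for t in taxa:
            row = rows_src[t]
            sub = "".join(row[c] for c in cols)
            chunks[t].append(revcomp(sub) if feat.strand == "-" else sub)
        partitions.append((feat.name, offset, offset + glen))
        offset += glen
    if not partitions:
        raise ValueError("no single-copy CDS genes in the reference annotation")
    return Supermatrix(
        taxa=taxa, rows=["".join(chunks[t]) for t in taxa], partitions=partitions
    )


# ---------------------------------------------------------------------------
# Distances


def _pair_stats(mat: np.ndarray):
    """Per-pattern difference/validity indicators for all taxon pairs."""
    k = mat.shape[0]
    patterns, inverse, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    gap = (patterns == ord("-")) | (patterns == ord("N"))
    diff = np.zeros((patterns.shape[0], len(pairs)), dtype=np.float64)
    valid = np.zeros_like(diff)
    for idx, (i, j) in enumerate(pairs):
        ok = ~(gap[:, i] | gap[:, j])
        valid[:, idx] = ok
        diff[:, idx] = ok & (patterns[:, i] != patterns[:, j])
    return diff, valid, pairs, counts


def _distances_from_counts(diff, valid, pairs, counts, k, model) -> np.ndarray:
    d_sums = counts @ diff
    v_sums = counts @ valid
    if np.any(v_sums == 0):
        raise ValueError("a taxon pair shares no comparable site")
    p = d_sums / v_sums
    if model == "jc69":
        if np.any(p >= 0.75):
            idx = int(np.argmax(p))
            raise ValueError(
                f"JC69 distance undefined (p={p[idx]:.3f} >= 0.75) for pair {pairs[idx]}"
            )
        p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    D = np.zeros((k, k))
    for (i, j), dij in zip(pairs, p):
        D[i, j] = D[j, i] = dij
    return D


def distance_matrix(matrix: Supermatrix, model: str = "jc69") -> np.ndarray:
    """Pairwise p- or JC69 distances with pairwise deletion of gap/N sites."""
    mat = matrix.matrix()
    diff, valid, pairs, counts = _pair_stats(mat)
    return _distances_from_counts(diff, valid, pairs, counts, mat.shape[0], model)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if not node.children:
                body = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.6g}"

        return fmt(self, True) + ";"


def _clades(node: TreeNode) -> list[frozenset]:
    """Leaf sets of every non-root internal edge (child side)."""
    out: list[tuple[TreeNode, frozenset]] = []

    def walk(n: TreeNode) -> frozenset:
        if not n.children:
            return frozenset([n.name])
        below = frozenset().union(*(walk(c) for c in n.children))
        out.append((n, below))
        return below

    walk(node)
    return out


def bipartitions(node: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, canonicalized to the side that
    excludes the lexicographically first leaf."""
    all_leaves = frozenset(node.leaf_names())
    anchor = min(all_leaves)
    parts: set[frozenset] = set()
    for _, below in _clades(node):
        side = below if anchor not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            parts.add(frozenset(side))
    return parts


@dataclass
class PhyloTree:
    root: TreeNode
    outgroup: str | None = None
    model: str = "jc69"
    bootstrap_n: int = 0

    def newick(self, with_support: bool = True) -> str:
        return self.root.newick(with_support=with_support)

    def bipartitions(self) -> set[frozenset]:
        return bipartitions(self.root)

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def _canonical(self, names) -> frozenset:
        all_leaves = frozenset(self.leaf_names())
        side = frozenset(names)
        return side if min(all_leaves) not in side else all_leaves - side

    def has_bipartition(self, names) -> bool:
        """True when the unrooted tree separates ``names`` from the rest."""
        return self._canonical(names) in self.bipartitions()

    def support_of(self, names) -> float | None:
        """Bootstrap support of the bipartition, or None when absent."""
        target = self._canonical(names)
        all_leaves = frozenset(self.leaf_names())
        for node, below in _clades(self.root):
            side = below if min(all_leaves) not in below else all_leaves - below
            if side == target:
                return node.support
        return None


def neighbor_joining(D: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei NJ; deterministic (ties break on the smallest pair index).

    Returns an unrooted tree represented with a trifurcating root (or a
    single edge for two taxa).  Negative branch lengths are clamped to 0.
    """
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 taxa")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(k)}
    D = {(i, j): float(D[i, j]) for i in range(k) for j in range(k) if i != j}
    active = list(range(k))
    nxt = k

    def d(i, j):
        return D[(i, j)] if i != j else 0.0

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d(i, j) - li
        ni, nj = nodes.pop(i), nodes.pop(j)
        ni.length = max(li, 0.0)
        nj.length = max(lj, 0.0)
        new = TreeNode(children=[ni, nj])
        for kk in active:
            if kk in (i, j):
                continue
            dk = 0.5 * (d(i, kk) + d(j, kk) - d(i, j))
            D[(nxt, kk)] = D[(kk, nxt)] = max(dk, 0.0)
        nodes[nxt] = new
        active = [a for a in active if a not in (i, j)] + [nxt]
        nxt += 1
    if len(active) == 2:
        i, j = active
        a, b = nodes[i], nodes[j]
        a.length = 0.0
        b.length = d(i, j)
        return TreeNode(children=[a, b])
    i, j, m = active
    # three-point formulas
    li = 0.5 * (d(i, j) + d(i, m) - d(j, m))
    lj = 0.5 * (d(i, j) + d(j, m) - d(i, m))
    lm = 0.5 * (d(i, m) + d(j, m) - d(i, j))
    for idx, ln in zip((i, j, m), (li, lj, lm)):
        nodes[idx].length = max(ln, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[m]])


def _reroot_on_leaf(root: TreeNode, leaf_name: str) -> TreeNode:
    """Root the unrooted tree on the edge leading to the outgroup leaf."""
    parent: dict[int, TreeNode | None] = {id(root): None}

    def index(n: TreeNode):
        for c in n.children:
            parent[id(c)] = n
            index(c)

    index(root)
    leaf = next(l for l in root.leaves() if l.name == leaf_name)

    def invert(node: TreeNode, exclude: TreeNode, carry: float) -> TreeNode:
        children = [c for c in node.children if c is not exclude]
        par = parent[id(node)]
        new = TreeNode(name=node.name, children=list(children), length=carry,
                       support=node.support)
        if par is not None:
            new.children.append(invert(par, node, node.length))
        return new

    p = parent[id(leaf)]
    if p is None:
        return root
    half = leaf.length / 2.0
    out_leaf = TreeNode(name=leaf.name, length=half)
    rest = invert(p, leaf, half)
    return TreeNode(children=[out_leaf, rest])


def nj_tree(
    matrix: Supermatrix,
    model: str = "jc69",
    bootstrap_n: int = 1000,
    seed: int = 0,
    outgroup: str | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports (bipartition frequency, 0-100).

    Bootstrap replicates resample alignment columns with a seeded generator;
    identical seeds give bit-identical results.  The tree is rooted on the
    outgroup when one is named.
    """
    mat = matrix.matrix()
    k, L = mat.shape
    if k < 3:
        raise ValueError("need >= 3 taxa for a tree")
    diff, valid, pairs, counts = _pair_stats(mat)
    D = _distances_from_counts(diff, valid, pairs, counts, k, model)
    taxa = list(matrix.taxa)
    main = neighbor_joining(D, taxa)
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        freq: dict[frozenset, int] = {}
        probs = counts / counts.sum()
        for _ in range(bootstrap_n):
            c = rng.multinomial(L, probs)
            try:
                Db = _distances_from_counts(diff, valid, pairs, c, k, model)
            except ValueError:  # a pair lost all its comparable sites
                continue
            rep = neighbor_joining(Db, taxa)
            for bp in bipartitions(rep):
                freq[bp] = freq.get(bp, 0) + 1
    if outgroup is not None:
        if outgroup not in taxa:
            raise ValueError(f"outgroup {outgroup!r} not among taxa")
        main = _reroot_on_leaf(main, outgroup)
    if bootstrap_n > 0:
        all_leaves = frozenset(taxa)
        anchor = min(all_leaves)
        for node, below in _clades(main):
            side = below if anchor not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1:
                node.support = round(100.0 * freq.get(frozenset(side), 0) / bootstrap_n, 1)
    return PhyloTree(root=main, outgroup=outgroup, model=model, bootstrap_n=bootstrap_n)
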