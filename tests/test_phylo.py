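import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastmarker.io_formats import GeneFeature, Plastome
from plastmarker.phylo import (
    Supermatrix,
    bipartitions,
    build_supermatrix,
    distance_matrix,
    extract_shared_genes,
    neighbor_joining,
    nj_tree,
)


def _annotated(tid: str, genes: dict[str, str], strand="+") -> Plastome:
    chunks = []
    feats = []
    for name, s in genes.items():
        chunks.append("TTTTTTTTTT")
        start = len("".join(chunks))
        chunks.append(s)
        feats.append(GeneFeature(name, "CDS", strand, ((start, start + len(s)),)))
    chunks.append("TTTTTTTTTT")
    return Plastome(id=tid, sequence="".join(chunks)).with_annotations(feats)


def test_shared_single_copy_genes():
    a = _annotated("a", {"g1": "ATGAAA", "g2": "ATGCCC"})
    b = _annotated("b", {"g1": "ATGAAA", "g2": "ATGCCA"})
    c = _annotated("c", {"g1": "ATGAAA"})  # lacks g2
    shared = extract_shared_genes([a, b, c])
    assert set(shared) == {"g1"}
    shared_ab = extract_shared_genes([a, b])
    assert set(shared_ab) == {"g1", "g2"}
    assert shared_ab["g2"] == {"a": "ATGCCC", "b": "ATGCCA"}


def test_ir_duplicated_genes_are_excluded():
    a = _annotated("a", {"g1": "ATGAAA"})
    dup = GeneFeature("g2", "CDS", "+", ((0, 6),), copy_tag="IR-duplicated")
    a = a.with_annotations(list(a.annotations) + [dup])
    assert set(extract_shared_genes([a])) == {"g1"}


def test_minus_strand_genes_are_spliced_on_coding_strand():
    a = _annotated("a", {"g1": "TTTCAT"}, strand="-")  # revcomp -> ATGAAA
    shared = extract_shared_genes([a])
    assert shared["g1"] == {"a": "ATGAAA"}


def test_supermatrix_shape_partitions_and_order_invariance():
    genes = {
        "g1": {"a": "A" * 30, "b": "A" * 29 + "C", "c": "A" * 30},
        "g2": {"a": "C" * 60, "b": "C" * 60, "c": "C" * 59 + "T"},
    }
    sm = build_supermatrix(genes)
    assert len(sm) == 90
    assert sm.partitions == [("g1", 0, 30), ("g2", 30, 90)]
    permuted = {g: dict(reversed(list(seqs.items()))) for g, seqs in genes.items()}
    sm2 = build_supermatrix(permuted)
    assert sm2.taxa == sm.taxa and sm2.rows == sm.rows


def test_nj_recovers_additive_four_taxon_tree():
    labels = ["A", "B", "C", "D"]
    D = np.array([
        [0, 2, 6, 6],
        [2, 0, 6, 6],
        [6, 6, 0, 4],
        [6, 6, 4, 0],
    ], dtype=float)
    tree = neighbor_joining(D, labels)
    assert frozenset({"A", "B"}) in {
        frozenset(side) for side in _sides(tree)
    }


def _sides(tree):
    all_leaves = frozenset(tree.leaf_names())
    out = []
    for bp in bipartitions(tree):
        out.append(bp)
        out.append(all_leaves - bp)
    return out


def test_three_taxa_closed_form_branch_lengths():
    labels = ["A", "B", "C"]
    D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
    tree = neighbor_joining(D, labels)
    lengths = {c.name: c.length for c in tree.children}
    assert lengths["A"] == pytest.approx(1.0)  # (3+5-6)/2
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(4.0)


def test_nj_matches_scikit_bio_on_random_matrices():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(42)
    for trial in range(8):
        k = int(rng.integers(4, 9))
        pts = rng.random((k, 6))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(k)]
        mine = neighbor_joining(D.copy(), labels)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        mine_bp = bipartitions(mine)
        theirs_bp = set()
        all_leaves = frozenset(labels)
        anchor = min(all_leaves)
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            side = below if anchor not in below else all_leaves - below
            if 1 < len(side) < k - 1:
                theirs_bp.add(frozenset(side))
        assert mine_bp == theirs_bp


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 100_000), st.integers(4, 8))
def test_nj_exact_on_random_additive_trees(seed, k):
    """On distances generated by a random binary tree with positive branch
    lengths, NJ recovers every bipartition of the generating tree."""
    rng = np.random.default_rng(seed)
    # random binary tree by leaf-edge splitting; node 0 is the root
    edges = {}  # node -> (parent, length)
    leaves = [1, 2, 3]
    for l in leaves:
        edges[l] = (0, rng.uniform(0.5, 2.0))
    nxt = 4
    while len(leaves) < k:
        target = leaves[rng.integers(0, len(leaves))]
        inner, leaf = nxt, nxt + 1
        nxt += 2
        edges[inner] = edges[target]
        edges[target] = (inner, rng.uniform(0.5, 2.0))
        edges[leaf] = (inner, rng.uniform(0.5, 2.0))
        leaves.append(leaf)

    def path_to_root(n):
        out = []
        while n in edges:
            par, ln = edges[n]
            out.append((n, ln))
            n = par
        return out

    D = np.zeros((k, k))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i >= j:
                continue
            pa = dict(path_to_root(a))
            pb = dict(path_to_root(b))
            d = sum(l for n, l in pa.items() if n not in pb)
            d += sum(l for n, l in pb.items() if n not in pa)
            D[i, j] = D[j, i] = d
    labels = [str(l) for l in leaves]
    tree = neighbor_joining(D, labels)
    # true bipartitions: leaves below each internal edge
    children = {}
    for n, (p, _) in edges.items():
        children.setdefault(p, []).append(n)

    def leaves_below(n):
        if n not in children:
            return {n}
        out = set()
        for c in children[n]:
            out |= leaves_below(c)
        return out

    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    true_bp = set()
    for n in children:
        below = frozenset(str(x) for x in leaves_below(n))
        side = below if anchor not in below else all_leaves - below
        if 1 < len(side) < k - 1:
            true_bp.add(side)
    assert true_bp <= bipartitions(tree)


def test_bootstrap_is_seed_reproducible_and_order_invariant():
    rows = {
        "a": "ACGTACGTACGTACGTACGT" * 5,
        "b": "ACGTACGTACGTACGAACGT" * 5,
        "c": "ACGTACTTACGTACGAACGT" * 5,
        "d": "ACGAACTTACGTACGAACGT" * 5,
    }
    sm = Supermatrix(taxa=list(rows), rows=list(rows.values()), partitions=[("g", 0, 100)])
    t1 = nj_tree(sm, bootstrap_n=100, seed=5)
    t2 = nj_tree(sm, bootstrap_n=100, seed=5)
    assert t1.newick() == t2.newick()
    t3 = nj_tree(sm, bootstrap_n=100, seed=6)
    assert t3.newick() != "" # different seed still yields a valid tree
    perm = ["c", "a", "d", "b"]
    smp = Supermatrix(taxa=perm, rows=[rows[t] for t in perm],
                      partitions=[("g", 0, 100)])
    tp = nj_tree(smp, bootstrap_n=100, seed=5)
    assert tp.bipartitions() == t1.bipartitions()


def test_jc69_undefined_distance_raises():
    rows = {"a": "AAAA", "b": "CCCC", "c": "GGGG"}
    sm = Supermatrix(taxa=list(rows), rows=list(rows.values()), partitions=[("g", 0, 4)])
    with pytest.raises(ValueError, match="JC69"):
        distance_matrix(sm, model="jc69")
    D = distance_matrix(sm, model="p")
    assert D[0, 1] == 1.0
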