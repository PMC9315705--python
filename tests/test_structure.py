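import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastmarker.io_formats import GeneFeature, Plastome, revcomp
from plastmarker.structure import (
    AmbiguousStructureError,
    StructureNotFoundError,
    canonicalize,
    detect_quadripartite,
    junction_report,
)

from .oracles import brute_longest_inverted_pair


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_toy(rng, lsc=600, ir=100, ssc=200):
    """LSC + IRb + SSC + revcomp(IRb), boundary extension broken."""
    while True:
        l, r, s = _random_seq(rng, lsc), _random_seq(rng, ir), _random_seq(rng, ssc)
        seq = l + r + s + revcomp(r)
        st_ = None
        try:
            st_ = detect_quadripartite(Plastome(id="t", sequence=seq), min_ir_len=ir // 2)
        except (StructureNotFoundError, AmbiguousStructureError):
            continue
        if st_.segment_lengths() == {"LSC": lsc, "IRb": ir, "SSC": ssc, "IRa": ir}:
            return seq
        # random flanks occasionally extend the IR by chance; redraw


def test_constructed_toy_segments_match_oracle():
    rng = np.random.default_rng(0)
    seq = make_toy(rng)
    st_ = detect_quadripartite(Plastome(id="t", sequence=seq), min_ir_len=50)
    assert st_.segment_lengths() == {"LSC": 600, "IRb": 100, "SSC": 200, "IRa": 100}
    best_len, pairs = brute_longest_inverted_pair(seq, 50)
    assert best_len == st_.ir_len
    assert len(pairs) == 1


def test_tiling_and_revcomp_invariants(tiny_sim):
    for g in [tiny_sim.reference] + tiny_sim.genomes:
        st_ = detect_quadripartite(g)
        assert st_.lsc_len + st_.ssc_len + 2 * st_.ir_len == len(g.sequence)
        canon = canonicalize(g, st_)
        irb = canon.sequence[st_.irb[0] : st_.irb[1]]
        ira = canon.sequence[st_.ira[0] : st_.ira[1]]
        assert ira == revcomp(irb)


def test_rotation_and_strand_invariance():
    rng = np.random.default_rng(1)
    seq = make_toy(rng)
    g = Plastome(id="t", sequence=seq)
    base = canonicalize(g, min_ir_len=50)
    for k in (7, 137, 512):
        rotated = Plastome(id="t", sequence=seq[k:] + seq[:k])
        canon = canonicalize(rotated, min_ir_len=50)
        assert canon.sequence == base.sequence
    flipped = Plastome(id="t", sequence=revcomp(seq))
    st_flip = detect_quadripartite(flipped, min_ir_len=50)
    assert st_flip.segment_lengths() == base.structure.segment_lengths()


def test_no_inverted_repeat_raises():
    rng = np.random.default_rng(2)
    seq = _random_seq(rng, 10_000)
    with pytest.raises(StructureNotFoundError):
        detect_quadripartite(Plastome(id="r", sequence=seq), min_ir_len=1000)


def test_equal_single_copy_segments_are_ambiguous():
    # dinucleotide single-copy segments prevent chance IR-boundary extension,
    # so both gaps stay exactly 300 bp and LSC/SSC cannot be labelled
    rng = np.random.default_rng(3)
    r = _random_seq(rng, 100)
    seq = "AC" * 150 + r + "AG" * 150 + revcomp(r)
    with pytest.raises(AmbiguousStructureError):
        detect_quadripartite(Plastome(id="t", sequence=seq), min_ir_len=50)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(300, 900), st.integers(60, 120),
       st.integers(100, 280))
def test_fuzzed_toys_agree_with_brute_force(seed, lsc, ir, ssc):
    """Detection equals the O(n^2) inverted-repeat oracle on small genomes."""
    rng = np.random.default_rng(seed)
    seq = make_toy(rng, lsc=lsc, ir=ir, ssc=ssc)
    st_ = detect_quadripartite(Plastome(id="t", sequence=seq), min_ir_len=ir // 2)
    best_len, pairs = brute_longest_inverted_pair(seq, ir // 2)
    assert st_.ir_len == best_len
    assert st_.lsc_len + st_.ssc_len + 2 * st_.ir_len == len(seq)


def test_junction_report_on_planted_genes(tiny_sim):
    canon = canonicalize(tiny_sim.reference)
    jc = junction_report(canon, canon.structure)
    gene, dist = jc.junctions["LSC/IRb"]
    assert (gene, dist) == ("rps19", 35)
    gene, dist = jc.junctions["IRb/SSC"]
    assert gene == "ndhF" and dist == -29
    gene, dist = jc.junctions["IRa/LSC"]
    assert gene == "rps19" and dist == 35  # mirrored IR copy


def test_gene_exactly_at_border_has_distance_zero():
    rng = np.random.default_rng(4)
    seq = make_toy(rng)
    g = Plastome(id="t", sequence=seq).with_annotations(
        [GeneFeature("geneA", "CDS", "+", ((600, 650),))]  # starts at LSC/IRb border
    )
    canon = canonicalize(g, min_ir_len=50)
    jc = junction_report(canon, canon.structure)
    assert jc.junctions["LSC/IRb"] == ("geneA", 0)
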