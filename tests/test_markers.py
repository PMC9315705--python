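import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastmarker.comparative import MultipleAlignment, diagnostic_variants
from plastmarker.io_formats import GroupMap, Plastome, revcomp
from plastmarker.markers import (
    ENZYMES,
    Amplicon,
    AmbiguousAmpliconError,
    EnzymeSpec,
    MarkerConfig,
    Primer,
    design_dcaps,
    design_indel_markers,
    digest,
    insilico_pcr,
    validate_marker,
)

from .oracles import brute_pcr_min_product


# ---------------------------------------------------------------------------
# Digestion


def test_digest_worked_example_taqi():
    assert digest("AAAATCGAAAAA", ENZYMES["TaqI"]) == [5, 7]


def test_digest_no_site_returns_whole_product():
    assert digest("AAAAAAAA", ENZYMES["TaqI"]) == [8]


def test_digest_xbai():
    seq = "GG" + "TCTAGA" + "CCCC"
    assert digest(seq, ENZYMES["XbaI"]) == [3, 9]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=300))
def test_fragments_always_sum_to_product_size(seq):
    for enz in ENZYMES.values():
        frags = digest(seq, enz)
        assert sum(frags) == len(seq)
        assert all(f > 0 for f in frags)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=300))
def test_blunt_cutter_revcomp_gives_reversed_fragments(seq):
    """With a blunt cut (offset = site length / 2) fragment lists mirror."""
    blunt = EnzymeSpec("EcoRV-like", "GATATC", 3)
    assert digest(revcomp(seq), blunt) == list(reversed(digest(seq, blunt)))


# ---------------------------------------------------------------------------
# In-silico PCR


def _template(seq, circular=True):
    return Plastome(id="t", sequence=seq, circular=circular)


def test_exact_primers_give_whole_template_product():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=50))
    amp = insilico_pcr(Primer(seq[:18]), Primer(revcomp(seq[-18:])), _template(seq, circular=False))
    assert amp is not None and amp.size == 50 and amp.sequence == seq


def test_product_spanning_circular_origin():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    fwd, rev = Primer(seq[300:318]), Primer(revcomp(seq[332:350]))
    base = insilico_pcr(fwd, rev, _template(seq))
    rotated = _template(seq[340:] + seq[:340])  # amplicon now wraps the origin
    wrapped = insilico_pcr(fwd, rev, rotated)
    assert base is not None and wrapped is not None
    assert wrapped.sequence == base.sequence == seq[300:350]


def test_no_binding_site_returns_none():
    amp = insilico_pcr(Primer("G" * 20), Primer("C" * 20), _template("AT" * 100))
    assert amp is None


def test_equal_minimal_products_raise_ambiguity():
    rng = np.random.default_rng(2)
    unit = "".join(rng.choice(list("ACGT"), size=120))
    seq = unit + unit  # every site exists twice at equal spacing
    fwd, rev = Primer(unit[:18]), Primer(revcomp(unit[60:78]))
    with pytest.raises(AmbiguousAmpliconError):
        insilico_pcr(fwd, rev, _template(seq))


def test_primer_mismatches_are_incorporated_into_product():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    fwd_seq = list(seq[:18])
    fwd_seq[5] = "A" if seq[5] != "A" else "C"  # one internal mismatch
    amp = insilico_pcr(Primer("".join(fwd_seq)), Primer(revcomp(seq[-18:])),
                       _template(seq, circular=False))
    assert amp is not None
    assert amp.sequence.startswith("".join(fwd_seq))
    assert amp.sequence.endswith(seq[-18:])


def test_exact_three_prime_terminus_is_required():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    bad = list(seq[:18])
    bad[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[-1]]
    amp = insilico_pcr(Primer("".join(bad)), Primer(revcomp(seq[-18:])),
                       _template(seq, circular=False))
    assert amp is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_pcr_agrees_with_bruteforce_placement_scan(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=250))
    i, j = sorted(rng.integers(0, 200, size=2))
    j = max(j, i + 40)
    fwd = Primer(seq[i : i + 18])
    rev = Primer(revcomp(seq[j : j + 18]))
    try:
        amp = insilico_pcr(fwd, rev, _template(seq))
    except AmbiguousAmpliconError:
        return
    expect = brute_pcr_min_product(seq, True, fwd.sequence, rev.sequence)
    if amp is None:
        assert expect is None
    else:
        assert amp.size == expect


# ---------------------------------------------------------------------------
# dCAPS design: hand-built toy


TOY_CFG = MarkerConfig(
    product_min=30, product_max=40, primer_min=15, primer_max=18,
    gc_min=0.0, gc_max=1.0, tm_min=0.0, tm_max=300.0, homopolymer_max=30,
)


def _toy_snp_setup(ref_allele="A", alt_allele="G"):
    head = "A" * 15 + "TAG"
    tail = "T" * 15
    ref_seq = head + ref_allele + tail
    alt_seq = head + alt_allele + tail
    genomes = [
        Plastome(id="gA", sequence=ref_seq, circular=False),
        Plastome(id="gB", sequence=alt_seq, circular=False),
    ]
    aln = MultipleAlignment.from_aligned(["gA", "gB"], [ref_seq, alt_seq], "gA")
    groups = GroupMap({"gA": "A", "gB": "B"})
    variants = diagnostic_variants(
        __import__("plastmarker.comparative", fromlist=["call_variants"]).call_variants(aln),
        groups,
    )
    return genomes, aln, groups, variants[0]


def test_dcaps_toy_fragments_16_18_vs_34():
    genomes, aln, groups, diag = _toy_snp_setup()
    designs, failures = design_dcaps(
        aln, diag, genomes, groups, enzymes=[ENZYMES["TaqI"]], config=TOY_CFG
    )
    assert designs, [f.reason for f in failures]
    d = designs[0]
    assert d.cut_allele == "A"
    assert d.introduced_mismatches == 1
    assert d.fwd.sequence == "A" * 15 + "TCG"  # TAG -> TCG completes T^CGA
    assert sorted(d.fragments_by_allele["A"]) == [16, 18]
    assert d.fragments_by_allele["G"] == (34,)
    res = validate_marker(d, genomes, groups, TOY_CFG)
    assert res.verdict


def test_caps_degenerate_when_site_needs_no_mismatch():
    head = "A" * 15 + "TCG"  # template already spells the TaqI site head
    tail = "T" * 15
    ref_seq, alt_seq = head + "A" + tail, head + "G" + tail
    genomes = [Plastome(id="gA", sequence=ref_seq, circular=False),
               Plastome(id="gB", sequence=alt_seq, circular=False)]
    aln = MultipleAlignment.from_aligned(["gA", "gB"], [ref_seq, alt_seq], "gA")
    groups = GroupMap({"gA": "A", "gB": "B"})
    from plastmarker.comparative import call_variants

    diag = diagnostic_variants(call_variants(aln), groups)[0]
    designs, _ = design_dcaps(aln, diag, genomes, groups,
                              enzymes=[ENZYMES["TaqI"]], config=TOY_CFG)
    assert any(d.is_caps and d.introduced_mismatches == 0 for d in designs)


# ---------------------------------------------------------------------------
# Designs on the synthetic complex


def test_planted_indel_yields_marker_with_planted_size_difference(tiny_bundle):
    sim = tiny_bundle["sim"]
    markers_, failures = design_indel_markers(
        tiny_bundle["aln"], tiny_bundle["diags"], tiny_bundle["genomes"], sim.groups
    )
    assert markers_, [f.reason for f in failures]
    by_locus = {m.locus_label: m for m in markers_}
    m = by_locus["rpl33-rps18"]  # planted 15 bp insertion in spontaneum+outgroup
    sizes = m.size_by_group
    assert max(sizes.values()) - min(sizes.values()) == 15
    assert m.category == "two-vs-rest"
    trnr = by_locus["trnR-rps14"]  # 26 bp and 16 bp insertions -> three sizes
    assert len(set(trnr.size_by_group.values())) == 3
    assert trnr.category == "three-way"


def test_small_indels_are_rejected_by_resolvability(tiny_bundle):
    sim = tiny_bundle["sim"]
    _, failures = design_indel_markers(
        tiny_bundle["aln"], tiny_bundle["diags"], tiny_bundle["genomes"], sim.groups
    )
    assert any("resolvability" in f.reason for f in failures)


def test_every_emitted_dcaps_is_allele_specific_and_self_validates(tiny_bundle):
    sim = tiny_bundle["sim"]
    snp_diags = [
        d for d in tiny_bundle["diags"]
        if d.variant.kind == "SNP" and len(set(d.allele_by_group.values())) == 2
        and d.variant.locus_label in ("trnG-trnM", "rbcL-psaI")
    ]
    assert len(snp_diags) == 2
    n_designs = 0
    for diag in snp_diags:
        designs, failures = design_dcaps(
            tiny_bundle["aln"], diag, tiny_bundle["genomes"], sim.groups
        )
        assert designs, [f.reason for f in failures]
        enzymes_hit = {d.enzyme.name for d in designs}
        assert enzymes_hit == {"TaqI", "XbaI"}  # the planted context admits both
        for d in designs:
            n_designs += 1
            for allele, frags in d.fragments_by_allele.items():
                assert sum(frags) == d.size_by_allele[allele]
            cut = [a for a, frags in d.fragments_by_allele.items() if len(frags) > 1]
            assert cut == [d.cut_allele]
            res = validate_marker(d, sim.genomes, sim.groups)
            assert res.verdict, res.reason
    assert n_designs >= 4


def test_validate_fails_on_within_group_variation():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    fwd, rev = Primer(seq[100:120]), Primer(revcomp(seq[220:240]))
    # one member of group A carries a deletion inside the amplicon
    broken = seq[:150] + seq[165:]
    genomes = [
        Plastome(id="a1", sequence=seq),
        Plastome(id="a2", sequence=broken),
        Plastome(id="b1", sequence=seq),
    ]
    groups = GroupMap({"a1": "A", "a2": "A", "b1": "B"})
    from plastmarker.markers import IndelMarker

    marker = IndelMarker(id="m", fwd=fwd, rev=rev, locus_label=None,
                         ref_interval=(100, 240), size_by_group={})
    res = validate_marker(marker, genomes, groups)
    assert not res.verdict
    assert "varies within group" in res.reason
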