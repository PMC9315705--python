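import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastmarker.alignment import CollinearityError, banded_align
from plastmarker.comparative import (
    MultipleAlignment,
    align_plastomes,
    call_variants,
    classify_regions,
    classify_position,
    diagnostic_variants,
    normalize_variant,
    region_identity,
)
from plastmarker.io_formats import GeneFeature, GroupMap, Plastome

from .oracles import nw_affine_score


# ---------------------------------------------------------------------------
# Banded aligner vs full-DP oracle


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=50),
       st.text(alphabet="ACGT", min_size=1, max_size=50))
def test_banded_score_matches_full_needleman_wunsch(a, b):
    if abs(len(a) - len(b)) > 40:
        return
    ra, rb, score = banded_align(a, b, band=60)
    assert score == nw_affine_score(a, b)
    assert ra.replace("-", "") == a and rb.replace("-", "") == b


def test_single_deletion_is_left_aligned_in_calls():
    aln = MultipleAlignment.from_aligned(
        ["ref", "s"], ["ACGTACGT", "ACG-ACGT"], "ref"
    )
    (v,) = call_variants(aln)
    assert (v.kind, v.ref_pos, v.ref_allele, v.alt_alleles) == ("InDel", 2, "GT", ("G",))


def test_collinearity_error_on_length_mismatch():
    a = Plastome(id="a", sequence="ACGT" * 300)
    b = Plastome(id="b", sequence="ACGT" * 200)
    with pytest.raises(CollinearityError):
        align_plastomes([a, b], "a")


# ---------------------------------------------------------------------------
# Variant calling


def _aln(rows: dict[str, str], ref="ref") -> MultipleAlignment:
    return MultipleAlignment.from_aligned(list(rows), list(rows.values()), ref)


def test_three_sequence_snp_example():
    aln = _aln({"ref": "AAAA", "s1": "AAAT", "s2": "AATT"})
    variants = call_variants(aln)
    assert [(v.kind, v.ref_pos) for v in variants] == [("SNP", 2), ("SNP", 3)]
    v2, v3 = variants
    assert v3.calls == {"s1": "T", "s2": "T", "ref": "A"}
    assert v2.calls == {"s1": "A", "s2": "T", "ref": "A"}


def test_identical_alignment_has_no_variants():
    assert call_variants(_aln({"ref": "ACGT" * 5, "s": "ACGT" * 5})) == []


def test_long_gap_run_is_one_event():
    ref = "ACGT" * 20
    gap_start = 13
    row = ref[:gap_start] + "-" * 27 + ref[gap_start + 27 :]
    variants = call_variants(_aln({"ref": ref, "s": row}))
    assert len(variants) == 1
    (v,) = variants
    assert v.kind == "InDel"
    assert len(v.ref_allele) - len(v.alt_alleles[0]) == 27


def test_gap_position_within_homopolymer_normalizes_identically():
    ref = "CCAAAAAG"
    left = "CC-AAAAG"
    right = "CCAAAA-G"
    v1 = call_variants(_aln({"ref": ref, "s": left}))[0]
    v2 = call_variants(_aln({"ref": ref, "s": right}))[0]
    assert (v1.ref_pos, v1.ref_allele, v1.alt_alleles) == (
        v2.ref_pos, v2.ref_allele, v2.alt_alleles
    )
    assert v1.ref_pos == 1  # shifted against the first C


def test_normalize_variant_at_origin():
    assert normalize_variant("AAAG", 0, "AA", "A") == (0, "AA", "A")


def test_calls_invariant_to_sample_order():
    rows = {"ref": "ACGTACGTAA", "s1": "ACGAACGTAA", "s2": "ACGTACGTTA"}
    v_fwd = call_variants(_aln(rows))
    rows_rev = {"ref": rows["ref"], "s2": rows["s2"], "s1": rows["s1"]}
    v_rev = call_variants(_aln(rows_rev))
    assert {(v.key(), tuple(sorted(v.calls.items()))) for v in v_fwd} == {
        (v.key(), tuple(sorted(v.calls.items()))) for v in v_rev
    }


def test_n_sites_are_excluded():
    variants = call_variants(_aln({"ref": "ACGT", "s": "ANGT"}))
    assert variants == []


def test_degap_roundtrip_on_synthetic_alignment(tiny_bundle):
    aln = tiny_bundle["aln"]
    for g in tiny_bundle["genomes"]:
        assert aln.degapped(g.id) == g.sequence


# ---------------------------------------------------------------------------
# Region classification


def test_classify_positions_on_synthetic_annotation(tiny_sim):
    ref = tiny_sim.reference
    ndhf = next(f for f in ref.annotations if f.name == "ndhF")
    assert classify_position(ref, ndhf.start + 5) == ("CDS", "ndhF")
    rps16 = next(f for f in ref.annotations if f.name == "rps16")
    intron_pos = rps16.parts[0][1] + 3  # inside the gap between the two exons
    assert classify_position(ref, intron_pos) == ("intron", "rps16")
    spacer_pos = (ndhf.end + next(
        f for f in ref.annotations if f.name == "rpl32"
    ).start) // 2
    assert classify_position(ref, spacer_pos) == ("intergenic", "ndhF-rpl32")


def test_classified_variants_carry_locus_labels(tiny_bundle):
    variants = tiny_bundle["variants"]
    assert all(v.region for v in variants)
    labels = {v.locus_label for v in variants if v.region == "intergenic"}
    assert any("-" in l for l in labels)


# ---------------------------------------------------------------------------
# Diagnostics


def _groups():
    return GroupMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


def test_within_group_polymorphism_is_not_diagnostic():
    aln = _aln({"ref": "AAAA", "a1": "AAAT", "a2": "AAAA", "b1": "AAAA", "b2": "AAAA"})
    variants = call_variants(aln)
    assert diagnostic_variants(variants, _groups()) == []


def test_fixed_difference_is_diagnostic():
    aln = _aln({"ref": "AAAA", "a1": "AAAT", "a2": "AAAT", "b1": "AAAA", "b2": "AAAA"})
    (d,) = diagnostic_variants(call_variants(aln), _groups())
    assert d.partition == (("A",), ("B",))
    assert d.category == "one-vs-rest"
    assert d.allele_by_group == {"A": "T", "B": "A"}


def test_three_allele_site_is_three_way(tiny_bundle):
    diags = tiny_bundle["diags"]
    planted = next(
        d for d in diags
        if d.variant.kind == "SNP" and len(set(d.allele_by_group.values())) == 3
    )
    assert planted.category == "three-way"
    assert len(planted.partition) == 3


def test_empty_group_raises():
    gm = GroupMap({"a1": "A"}, group_order=["A", "B"])
    with pytest.raises(ValueError, match="no samples"):
        diagnostic_variants([], gm)


# ---------------------------------------------------------------------------
# Region identity


def test_region_identity_hand_computed():
    seq = "A" * 100 + "C" * 100
    feats = [GeneFeature("g1", "CDS", "+", ((0, 100),))]
    ref = Plastome(id="ref", sequence=seq).with_annotations(feats)
    other = "A" * 50 + "G" + "A" * 49 + "C" * 100  # 1 mismatch inside the CDS
    aln = _aln({"ref": seq, "s": other})
    ident = region_identity(aln, ref)
    assert ident["exon"] == (99.0, 0.0)
    assert ident["intergenic"] == (100.0, 0.0)


def test_identical_rows_are_fully_identical(tiny_sim):
    seq = tiny_sim.reference.sequence
    aln = _aln({"ref": seq, "s": seq})
    ident = region_identity(aln, tiny_sim.reference)
    for cls, (mean, sd) in ident.items():
        assert mean == 100.0 and sd == 0.0
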