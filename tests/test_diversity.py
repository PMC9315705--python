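import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastmarker.comparative import MultipleAlignment, align_plastomes
from plastmarker.diversity import DiversityConfig, overall_pi, sliding_pi, summarize_pi
from plastmarker.simulate import simulate, tiny_config
from plastmarker.structure import detect_quadripartite

from .oracles import brute_window_pi


def _aln(rows: dict[str, str], ref=None) -> MultipleAlignment:
    ids = list(rows)
    return MultipleAlignment.from_aligned(ids, list(rows.values()), ref or ids[0])


def test_hand_computed_pi_three_sequences():
    aln = _aln({"a": "AAAA", "b": "AAAT", "c": "AATT"})
    profile = sliding_pi(aln, DiversityConfig(window=4, step=4))
    assert profile.pi[0] == pytest.approx((0.25 + 0.5 + 0.25) / 3)
    assert overall_pi(aln) == pytest.approx(1 / 3)


def test_identical_sequences_have_zero_pi():
    aln = _aln({"a": "ACGT" * 300, "b": "ACGT" * 300})
    profile = sliding_pi(aln)
    assert np.all(profile.pi == 0.0)


def test_single_difference_gives_one_over_window():
    seq = "ACGT" * 250
    other = seq[:700] + ("A" if seq[700] != "A" else "C") + seq[701:]
    aln = _aln({"a": seq, "b": other})
    profile = sliding_pi(aln, DiversityConfig(window=500, step=250))
    for s, e, pi in zip(profile.window_starts, profile.window_ends, profile.pi):
        if s <= 700 < e:
            assert pi == pytest.approx(1 / 500)
        else:
            assert pi == 0.0


def test_window_larger_than_alignment_warns_and_uses_whole():
    aln = _aln({"a": "ACGTACGT", "b": "ACGAACGT"})
    with pytest.warns(UserWarning, match="single whole-alignment window"):
        profile = sliding_pi(aln, DiversityConfig(window=500, step=250))
    assert len(profile) == 1
    assert profile.pi[0] == pytest.approx(1 / 8)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 6), st.integers(40, 200),
       st.booleans())
def test_sliding_pi_matches_brute_force(seed, k, length, complete):
    """Window Pi equals the all-pairs Hamming oracle, with gaps and N."""
    rng = np.random.default_rng(seed)
    rows = {}
    for i in range(k):
        chars = rng.choice(list("ACGT-N"), size=length, p=[0.3, 0.3, 0.15, 0.15, 0.05, 0.05])
        rows[f"s{i}"] = "".join(chars)
    aln = _aln(rows)
    cfg = DiversityConfig(window=50, step=25, complete_deletion=complete)
    profile = sliding_pi(aln, cfg)
    for s, e, pi in zip(profile.window_starts, profile.window_ends, profile.pi):
        expect = brute_window_pi(list(rows.values()), int(s), int(e), complete)
        if math.isnan(expect):
            assert math.isnan(pi)
        else:
            assert pi == pytest.approx(expect)


def test_pi_invariant_to_row_order():
    rows = {"a": "ACGTACGTAC", "b": "ACGAACGTAC", "c": "ACGTACGTCC"}
    p1 = sliding_pi(_aln(rows), DiversityConfig(window=10, step=10)).pi
    rows_r = {"c": rows["c"], "a": rows["a"], "b": rows["b"]}
    p2 = sliding_pi(_aln(rows_r, ref="a"), DiversityConfig(window=10, step=10)).pi
    assert np.allclose(p1, p2)


def test_concerted_ir_gives_exactly_zero_ir_pi(tiny_bundle):
    aln, struct = tiny_bundle["aln"], tiny_bundle["structure"]
    sim = tiny_bundle["sim"]
    profile = sliding_pi(aln)
    summary = summarize_pi(aln, profile, struct, groups=sim.groups)
    assert summary["regions"]["IR"]["mean"] == 0.0
    assert summary["regions"]["IR"]["max"] == 0.0
    assert summary["regions"]["LSC"]["mean"] > 0.0


def test_private_mutations_give_unique_nonzero_group_pi():
    cfg = tiny_config(5, samples_per_species=2,
                      private_budgets=(("robustum", (3, 0)),))
    sim = simulate(cfg)
    aln = align_plastomes([sim.reference] + sim.genomes, "REF")
    struct = detect_quadripartite(sim.reference)
    summary = summarize_pi(aln, sliding_pi(aln), struct, groups=sim.groups)
    per_group = summary["per_group"]
    assert per_group["robustum"] > 0.0
    for grp, pi in per_group.items():
        if grp != "robustum":
            assert pi == 0.0
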