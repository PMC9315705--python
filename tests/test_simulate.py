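import numpy as np
import pytest

from plastmarker.comparative import align_plastomes, call_variants
from plastmarker.io_formats import revcomp
from plastmarker.simulate import (
    BranchSpec,
    SimConfig,
    default_species_tree,
    simulate,
    tiny_config,
)
from plastmarker.ssr import scan_ssrs
from plastmarker.structure import detect_quadripartite


def test_genome_length_is_sum_of_segments(tiny_sim):
    cfg = tiny_sim.config
    assert len(tiny_sim.reference.sequence) == cfg.lsc_len + cfg.ssc_len + 2 * cfg.ir_len


def test_default_budgets_match_study_counts():
    tree = default_species_tree(1)
    paths = {}

    def walk(node, snps, indels):
        snps, indels = snps + node.snps, indels + node.indels
        if not node.children:
            paths[node.name] = (snps, indels)
        for c in node.children:
            walk(c, snps, indels)

    walk(tree, 0, 0)
    assert paths["spontaneum"] == (68, 43)
    assert paths["robustum"] == (20, 12)
    assert paths["sinense"] == (22, 10)
    assert paths["barberi"] == (22, 10)
    assert paths["officinarum"] == (10, 5)


def test_same_seed_is_byte_identical():
    a = simulate(tiny_config(3))
    b = simulate(tiny_config(3))
    assert a.reference.sequence == b.reference.sequence
    assert [(g.id, g.sequence) for g in a.genomes] == [
        (g.id, g.sequence) for g in b.genomes
    ]
    assert a.truth.per_sample == b.truth.per_sample
    c = simulate(tiny_config(4))
    assert c.reference.sequence != a.reference.sequence


def test_ir_mirror_invariant_holds_for_every_sample(tiny_sim):
    for g in [tiny_sim.reference] + tiny_sim.genomes:
        st = detect_quadripartite(g)
        seq = g.sequence
        irb = seq[st.irb[0] : st.irb[1]]
        ira = seq[st.ira[0] : st.ira[1]]
        assert ira == revcomp(irb), g.id


def test_detection_recovers_configured_segment_lengths(tiny_sim):
    cfg = tiny_sim.config
    st = detect_quadripartite(tiny_sim.reference)
    assert st.segment_lengths() == {
        "LSC": cfg.lsc_len, "IRb": cfg.ir_len, "SSC": cfg.ssc_len, "IRa": cfg.ir_len
    }


def test_planted_ssrs_are_recovered_at_their_positions(tiny_sim):
    found = {(r.start, r.motif, r.copies) for r in scan_ssrs(tiny_sim.reference)}
    for planted in tiny_sim.truth.planted_ssrs:
        assert planted in found


def test_zero_budgets_reproduce_the_ancestor():
    tree = BranchSpec(
        name="root",
        children=(BranchSpec("only", snps=0, indels=0, samples=2),),
    )
    cfg = tiny_config(2, species_tree=tree, planted_snps=(), planted_indels=())
    sim = simulate(cfg)
    for g in sim.genomes:
        assert g.sequence == sim.reference.sequence


def test_truth_reproduces_emitted_sequences(tiny_sim):
    ref = tiny_sim.reference.sequence
    for g in tiny_sim.genomes:
        seq = ref
        for ev in sorted(tiny_sim.truth.per_sample[g.id], key=lambda e: e.pos,
                         reverse=True):
            assert seq[ev.pos : ev.pos + len(ev.ref)] == ev.ref
            seq = seq[: ev.pos] + ev.alt + seq[ev.pos + len(ev.ref) :]
        assert seq == g.sequence


def test_unmirrored_ir_mutations_break_the_invariant():
    tree = BranchSpec(
        name="root",
        children=(BranchSpec("only", snps=40, indels=0, samples=1),),
    )
    base = dict(species_tree=tree, planted_snps=(), planted_indels=(),
                allow_ir_mutations=True)
    broken = simulate(tiny_config(6, mirror_ir=False, **base))
    cfg = broken.config
    irb = slice(cfg.lsc_len, cfg.lsc_len + cfg.ir_len)
    ira = slice(cfg.lsc_len + cfg.ir_len + cfg.ssc_len, None)
    g = broken.genomes[0]
    assert g.sequence[ira] != revcomp(g.sequence[irb])
    mirrored = simulate(tiny_config(6, mirror_ir=True, **base))
    g = mirrored.genomes[0]
    assert g.sequence[ira] == revcomp(g.sequence[irb])


def test_group_map_covers_every_sample(tiny_sim):
    tiny_sim.groups.validate_cover(g.id for g in tiny_sim.genomes)
    assert set(tiny_sim.groups.group_order) == {
        "officinarum", "robustum", "sinense", "barberi", "spontaneum", "tripidium"
    }


def test_exact_budget_counts_in_truth():
    sim = simulate(tiny_config(8, samples_per_species=1))
    tree = sim.config.tree()
    totals = {}

    def walk(node, snps, indels):
        snps, indels = snps + node.snps, indels + node.indels
        if not node.children:
            totals[node.name] = (snps, indels)
        for c in node.children:
            walk(c, snps, indels)

    walk(tree, 0, 0)
    for sid, evs in sim.truth.per_sample.items():
        species = sim.groups.group_of(sid)
        n_snp = sum(e.kind == "SNP" for e in evs)
        n_indel = sum(e.kind == "InDel" for e in evs)
        exp_snp, exp_indel = totals[species]
        # planted diagnostics are folded into the budgets by deduction
        assert (n_snp, n_indel) == (exp_snp, exp_indel), sid
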