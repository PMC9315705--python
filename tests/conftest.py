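import pytest

from plastmarker.comparative import (
    align_plastomes,
    call_variants,
    classify_regions,
    diagnostic_variants,
)
from plastmarker.simulate import simulate, tiny_config
from plastmarker.structure import detect_quadripartite


@pytest.fixture(scope="session")
def tiny_sim():
    """Desk-scale synthetic complex: 2 samples per species + outgroup."""
    return simulate(tiny_config(1, samples_per_species=2))


@pytest.fixture(scope="session")
def tiny_bundle(tiny_sim):
    """Aligned + called + classified view of the tiny simulation."""
    genomes = [tiny_sim.reference] + tiny_sim.genomes
    aln = align_plastomes(genomes, "REF")
    variants = classify_regions(call_variants(aln), tiny_sim.reference)
    diags = diagnostic_variants(variants, tiny_sim.groups)
    struct = detect_quadripartite(tiny_sim.reference)
    return dict(
        sim=tiny_sim, genomes=genomes, aln=aln, variants=variants,
        diags=diags, structure=struct,
    )
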