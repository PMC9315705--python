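"""Synthetic plastome evolution with machine-readable ground truth.

The generator emulates the statistical structure of a plastid species
complex: a quadripartite ancestor (default LSC 83,000 / SSC 12,500 /
IR 22,800 bp, echoing the real genomes' scale) with a plausible gene layout,
IRa constructed as the exact reverse complement of IRb, planted
microsatellites, and a species tree whose branches carry SNP/InDel budgets.
Default per-species totals against the reference are 68/43 (spontaneum,
including fixed 27 bp and 50 bp insertions), 20/12 (robustum), 22/10
(sinense and barberi) and 10/5 (officinarum), with a distant outgroup.

Mutations are placed uniformly in single-copy regions, outside forbidden
zones (planted SSRs, conserved flanks around planted diagnostic sites), with
transition:transversion weights 2:1 and geometric InDel lengths (mean 3).
The observed data this emulates shows zero IR variation across samples, so
by default no mutations land in the IRs at all; when ``allow_ir_mutations``
is set, IR SNPs are mirrored to the other copy (concerted evolution) unless
``mirror_ir`` is disabled for negative tests.

Every emitted difference is recorded in a truth table in normalized
(left-aligned) reference coordinates, so variant-calling recall/precision
and diagnostic recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .comparative import normalize_variant
from .io_formats import GeneFeature, GroupMap, Plastome, revcomp

__all__ = [
    "BranchSpec",
    "PlantedSNP",
    "PlantedInDel",
    "PlantedSSR",
    "SimConfig",
    "TruthVariant",
    "SyntheticTruth",
    "SimulationResult",
    "default_species_tree",
    "simulate_ancestor",
    "evolve",
    "simulate",
    "tiny_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_P = np.array([0.31, 0.19, 0.19, 0.31])  # ~38% GC, plastome-like
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class BranchSpec:
    """One branch of the species tree with its mutation budget.

    ``snps``/``indels`` count the random events private to this branch;
    planted diagnostic events assigned to the branch are extra and are
    deducted by the caller when exact per-species totals matter.
    ``fixed_insertions`` forces insertions of the given lengths among the
    branch's InDel events.  Leaves carry ``samples`` emitted genomes.
    """

    name: str
    snps: int = 0
    indels: int = 0
    fixed_insertions: tuple[int, ...] = ()
    samples: int = 0
    children: tuple["BranchSpec", ...] = ()

    def leaves(self) -> list["BranchSpec"]:
        if not self.children:
            return [self]
        out: list[BranchSpec] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class PlantedSNP:
    """A diagnostic SNP at a named intergenic spacer.

    ``allele_by_group`` lists non-reference carrier groups only; every other
    group keeps ``ref_base``.  The 5 bp of 5' context written into the
    ancestor ("TGTAG") admits both TaqI and XbaI dCAPS designs with one
    introduced mismatch when the alternate allele is A.
    """

    spacer: str
    ref_base: str
    allele_by_group: tuple[tuple[str, str], ...]
    context5: str = "TGTAG"


@dataclass(frozen=True)
class PlantedInDel:
    """A diagnostic insertion at a named spacer; carriers share one string
    when their lengths agree."""

    spacer: str
    insert_len_by_group: tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class PlantedSSR:
    spacer: str
    motif: str
    copies: int


def default_species_tree(samples_per_species: int = 2, budget_scale: float = 1.0) -> BranchSpec:
    k = samples_per_species

    def s(x: int) -> int:
        return max(1, round(x * budget_scale)) if x else 0

    if budget_scale != 1.0:
        full = default_species_tree(samples_per_species)

        def rescale(node: BranchSpec) -> BranchSpec:
            return replace(
                node,
                snps=s(node.snps),
                indels=max(s(node.indels), len(node.fixed_insertions)),
                children=tuple(rescale(c) for c in node.children),
            )

        return rescale(full)
    return BranchSpec(
        name="root",
        children=(
            BranchSpec(
                name="n_core",
                snps=5, indels=2,
                children=(
                    BranchSpec("officinarum", snps=5, indels=3, samples=k),
                    BranchSpec("robustum", snps=15, indels=10, samples=k),
                    BranchSpec(
                        name="n_rest",
                        snps=5, indels=1,
                        children=(
                            BranchSpec(
                                name="n_sinbar",
                                snps=8, indels=4,
                                children=(
                                    BranchSpec("sinense", snps=4, indels=3, samples=k),
                                    BranchSpec("barberi", snps=4, indels=3, samples=k),
                                ),
                            ),
                            BranchSpec(
                                name="n_wild",
                                snps=8, indels=2,
                                children=(
                                    BranchSpec(
                                        "spontaneum", snps=50, indels=38,
                                        fixed_insertions=(27, 50), samples=k,
                                    ),
                                    BranchSpec("tripidium", snps=300, indels=40, samples=1),
                                ),
                            ),
                        ),
                    ),
                ),
            ),
        ),
    )


def phylo_recovery_tree(samples_per_species: int = 1, budget_scale: float = 1.0
                        ) -> BranchSpec:
    """Divergence-scale variant of the species tree for topology recovery.

    The intra-complex budgets above mirror the handful of fixed differences
    between six nearly identical species; concatenated-gene phylogenies are
    estimated on panels spanning genera, where whole-plastome identity drops
    to ~98% (thousands of substitutions on the deepest path).  This tree
    keeps the same shape with branch budgets at that observed divergence
    scale, so internal branches carry enough signal that distance noise from
    the long outgroup branch does not mask them.
    """
    k = samples_per_species

    def s(x: int) -> int:
        return max(1, round(x * budget_scale))

    return BranchSpec(
        name="root",
        children=(
            BranchSpec(
                name="n_core", snps=s(200), indels=s(5),
                children=(
                    BranchSpec("officinarum", snps=s(150), indels=s(5), samples=k),
                    BranchSpec("robustum", snps=s(200), indels=s(5), samples=k),
                    BranchSpec(
                        name="n_rest", snps=s(300), indels=s(5),
                        children=(
                            BranchSpec(
                                name="n_sinbar", snps=s(300), indels=s(5),
                                children=(
                                    BranchSpec("sinense", snps=s(150), indels=s(5), samples=k),
                                    BranchSpec("barberi", snps=s(150), indels=s(5), samples=k),
                                ),
                            ),
                            BranchSpec(
                                name="n_wild", snps=s(300), indels=s(5),
                                children=(
                                    BranchSpec("spontaneum", snps=s(400), indels=s(10), samples=k),
                                    BranchSpec("tripidium", snps=s(1500), indels=s(30), samples=1),
                                ),
                            ),
                        ),
                    ),
                ),
            ),
        ),
    )


_DEFAULT_PLANTED_SNPS = (
    PlantedSNP("trnG-trnM", "G", (("robustum", "A"),)),
    PlantedSNP("rbcL-psaI", "G", (("sinense", "A"), ("barberi", "A"))),
    PlantedSNP("psbM-petN", "G", (("spontaneum", "A"), ("tripidium", "T"))),
)

_DEFAULT_PLANTED_INDELS = (
    PlantedInDel("rpl33-rps18", (("spontaneum", 15), ("tripidium", 15))),
    PlantedInDel("trnR-rps14", (("officinarum", 26), ("tripidium", 16))),
    PlantedInDel("rps16-trnQ", (("tripidium", 29),)),
)

_DEFAULT_PLANTED_SSRS = (
    PlantedSSR("psbA-matK", "A", 12),
    PlantedSSR("rpoB-rpoC1", "T", 12),
    PlantedSSR("atpI-atpH", "TA", 6),
    PlantedSSR("psaA-ycf3", "CT", 5),
    PlantedSSR("ycf4-cemA", "AAG", 5),
    PlantedSSR("clpP-psbB", "ATAG", 4),
)


@dataclass(frozen=True)
class SimConfig:
    seed: int
    lsc_len: int = 83_000
    ssc_len: int = 12_500
    ir_len: int = 22_800
    species_tree: BranchSpec | None = None
    samples_per_species: int = 2
    planted_snps: tuple[PlantedSNP, ...] = _DEFAULT_PLANTED_SNPS
    planted_indels: tuple[PlantedInDel, ...] = _DEFAULT_PLANTED_INDELS
    planted_ssrs: tuple[PlantedSSR, ...] = _DEFAULT_PLANTED_SSRS
    private_budgets: tuple[tuple[str, tuple[int, int]], ...] = ()
    ts_tv_weight: float = 2.0
    indel_mean_len: float = 3.0
    allow_ir_mutations: bool = False
    mirror_ir: bool = True
    diag_flank: int = 200
    gene_scale_div: int = 1  # divide template gene/intron lengths (desk-scale runs)

    def tree(self) -> BranchSpec:
        return self.species_tree or default_species_tree(self.samples_per_species)

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class TruthVariant:
    kind: str  # SNP | InDel
    pos: int
    ref: str
    alt: str

    def key(self) -> tuple:
        return (self.kind, self.pos, self.ref, self.alt)


@dataclass
class SyntheticTruth:
    per_sample: dict[str, list[TruthVariant]]
    planted_ssrs: list[tuple[int, str, int]]  # (start, motif, copies)
    diagnostic_snps: list[dict]
    diagnostic_indels: list[dict]
    tree_newick: str


@dataclass
class SimulationResult:
    reference: Plastome  # annotated ancestor, id 'REF'
    genomes: list[Plastome]
    groups: GroupMap
    truth: SyntheticTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Gene layout
#
# (name, kind, strand, exon lengths, intron lengths); spacers between
# consecutive genes are addressable as "left-right" for planting.

_LSC_TEMPLATE = [
    ("psbA", "CDS", "-", (1062,), ()),
    ("matK", "CDS", "-", (1530,), ()),
    ("rps16", "CDS", "-", (40, 227), (860,)),
    ("trnQ", "tRNA", "-", (72,), ()),
    ("psbK", "CDS", "+", (186,), ()),
    ("trnS", "tRNA", "-", (88,), ()),
    ("psbD", "CDS", "+", (1062,), ()),
    ("psbC", "CDS", "+", (1386,), ()),
    ("trnG", "tRNA", "+", (71,), ()),
    ("trnM", "tRNA", "+", (73,), ()),
    ("psbM", "CDS", "-", (105,), ()),
    ("petN", "CDS", "+", (90,), ()),
    ("trnC", "tRNA", "+", (71,), ()),
    ("rpoB", "CDS", "-", (3213,), ()),
    ("rpoC1", "CDS", "-", (2043,), ()),
    ("rpoC2", "CDS", "-", (4140,), ()),
    ("rps2", "CDS", "-", (711,), ()),
    ("atpI", "CDS", "-", (744,), ()),
    ("atpH", "CDS", "-", (246,), ()),
    ("atpF", "CDS", "-", (145, 410), (700,)),
    ("atpA", "CDS", "-", (1524,), ()),
    ("trnR", "tRNA", "+", (72,), ()),
    ("rps14", "CDS", "-", (303,), ()),
    ("psaB", "CDS", "-", (2205,), ()),
    ("psaA", "CDS", "-", (2253,), ()),
    ("ycf3", "CDS", "-", (124, 230, 153), (730, 740)),
    ("rps4", "CDS", "-", (606,), ()),
    ("trnT", "tRNA", "+", (73,), ()),
    ("trnF", "tRNA", "+", (73,), ()),
    ("ndhJ", "CDS", "-", (477,), ()),
    ("ndhK", "CDS", "-", (678,), ()),
    ("ndhC", "CDS", "-", (363,), ()),
    ("trnV", "tRNA", "-", (38, 37), (570,)),
    ("atpE", "CDS", "+", (411,), ()),
    ("atpB", "CDS", "+", (1497,), ()),
    ("rbcL", "CDS", "+", (1431,), ()),
    ("psaI", "CDS", "+", (111,), ()),
    ("ycf4", "CDS", "+", (555,), ()),
    ("cemA", "CDS", "+", (690,), ()),
    ("petA", "CDS", "+", (963,), ()),
    ("psbJ", "CDS", "-", (123,), ()),
    ("psbL", "CDS", "-", (117,), ()),
    ("psbF", "CDS", "-", (120,), ()),
    ("psbE", "CDS", "-", (252,), ()),
    ("petL", "CDS", "+", (96,), ()),
    ("petG", "CDS", "+", (114,), ()),
    ("trnW", "tRNA", "-", (74,), ()),
    ("trnP", "tRNA", "-", (74,), ()),
    ("psaJ", "CDS", "+", (129,), ()),
    ("rpl33", "CDS", "+", (201,), ()),
    ("rps18", "CDS", "+", (306,), ()),
    ("rpl20", "CDS", "-", (354,), ()),
    ("rps12", "CDS", "-", (114, 232), (540,)),
    ("clpP", "CDS", "-", (591,), ()),
    ("psbB", "CDS", "+", (1527,), ()),
    ("psbT", "CDS", "+", (108,), ()),
    ("psbH", "CDS", "+", (222,), ()),
    ("petB", "CDS", "+", (648,), ()),
    ("petD", "CDS", "+", (483,), ()),
    ("rpoA", "CDS", "-", (1014,), ()),
    ("rps11", "CDS", "-", (417,), ()),
    ("rpl36", "CDS", "-", (114,), ()),
    ("rps8", "CDS", "-", (402,), ()),
    ("rpl14", "CDS", "-", (369,), ()),
    ("rpl16", "CDS", "-", (408,), ()),
    ("rps3", "CDS", "-", (657,), ()),
    ("rpl22", "CDS", "-", (456,), ()),
]

_SSC_TEMPLATE = [
    ("rpl32", "CDS", "+", (171,), ()),
    ("trnL", "tRNA", "+", (80,), ()),
    ("ccsA", "CDS", "+", (963,), ()),
    ("ndhD", "CDS", "-", (1503,), ()),
    ("psaC", "CDS", "-", (246,), ()),
    ("ndhE", "CDS", "-", (306,), ()),
    ("ndhA", "CDS", "-", (553, 540), (1080,)),
    ("ndhH", "CDS", "-", (1182,), ()),
    ("rps15", "CDS", "-", (273,), ()),
]

# IR genes are given as offsets inside IRb; rps19 sits wholly inside the IR,
# 35 bp from the LSC/IRb border.
_IR_TEMPLATE = [
    ("rps19", "CDS", "-", (279,), ()),
    ("rpl2", "CDS", "-", (393, 434), (660,)),
    ("rpl23", "CDS", "-", (282,), ()),
    ("trnI", "tRNA", "-", (74,), ()),
    ("ndhB", "CDS", "-", (775, 756), (680,)),
    ("rps7", "CDS", "-", (468,), ()),
    ("rrn16", "rRNA", "+", (1490,), ()),
    ("trnA", "tRNA", "+", (73,), ()),
    ("rrn23", "rRNA", "+", (2810,), ()),
    ("rrn4.5", "rRNA", "+", (95,), ()),
    ("rrn5", "rRNA", "+", (121,), ()),
    ("trnN", "tRNA", "-", (72,), ()),
]

NDHF_IR_OVERHANG = 29  # bp of ndhF inside IRb at the IRb/SSC junction
RPS19_OFFSET = 35      # bp from the LSC/IRb border to rps19


def _layout_segment(template, seg_start: int, seg_len: int, lead: int = 150
                    ) -> tuple[list[GeneFeature], dict[str, int]]:
    """Place genes in order with evenly sized spacers; return features and
    spacer midpoints keyed 'left-right'."""
    footprint = sum(sum(ex) + sum(intr) for _, _, _, ex, intr in template)
    gaps = len(template)
    free = seg_len - footprint - lead
    if free < gaps * 40:
        raise ValueError(f"segment of {seg_len} bp too small for the gene template")
    gap = free // gaps
    feats: list[GeneFeature] = []
    spacers: dict[str, int] = {}
    pos = seg_start + lead
    prev_name = None
    prev_end = None
    for name, kind, strand, exons, introns in template:
        if prev_name is not None:
            spacers[f"{prev_name}-{name}"] = (prev_end + pos) // 2
        parts = []
        p = pos
        for i, ex in enumerate(exons):
            parts.append((p, p + ex))
            p += ex
            if i < len(introns):
                p += introns[i]
        feats.append(GeneFeature(name=name, kind=kind, strand=strand, parts=tuple(parts)))
        prev_name, prev_end = name, p
        pos = p + gap
    return feats, spacers


def _mirror_ir_interval(iv: tuple[int, int], lsc: int, ir: int, ssc: int, n: int
                        ) -> tuple[int, int]:
    a, b = iv
    return (n - (b - lsc), n - (a - lsc))


def _scaled(template, div: int):
    if div <= 1:
        return template
    return [
        (
            name, kind, strand,
            tuple(max(24, e // div) for e in exons),
            tuple(max(20, i // div) for i in introns),
        )
        for name, kind, strand, exons, introns in template
    ]


def build_annotations(config: SimConfig) -> tuple[list[GeneFeature], dict[str, int]]:
    """Gene features and spacer-midpoint registry for the ancestor layout."""
    lsc, ssc, ir = config.lsc_len, config.ssc_len, config.ir_len
    div = config.gene_scale_div
    n = config.genome_length
    irb_start = lsc
    ssc_start = lsc + ir
    feats, spacers = _layout_segment(_scaled(_LSC_TEMPLATE, div), 0, lsc)
    # ndhF spans the IRb/SSC junction, extending into IRb
    ndhf_len = max(2220 // div, 120)
    ndhf = GeneFeature(
        name="ndhF", kind="CDS", strand="-",
        parts=((ssc_start - NDHF_IR_OVERHANG, ssc_start - NDHF_IR_OVERHANG + ndhf_len),),
    )
    feats.append(ndhf)
    ssc_feats, ssc_spacers = _layout_segment(
        _SSC_TEMPLATE if div <= 1 else _scaled(_SSC_TEMPLATE, div),
        ssc_start + ndhf_len, ssc - ndhf_len - max(300 // div, 60), lead=max(120 // div, 40),
    )
    spacers.update(ssc_spacers)
    spacers["ndhF-rpl32"] = (ndhf.end + ssc_feats[0].start) // 2
    feats.extend(ssc_feats)
    # IRb genes; rps19 fixed at the LSC border, the rest laid out after it
    rps19_len = max(279 // div, 60)
    rps19 = GeneFeature(
        name="rps19", kind="CDS", strand="-",
        parts=((irb_start + RPS19_OFFSET, irb_start + RPS19_OFFSET + rps19_len),),
    )
    ir_rest, _ = _layout_segment(
        _scaled(_IR_TEMPLATE[1:], div), rps19.end + max(200 // div, 50),
        ir - (rps19.end + max(200 // div, 50) - irb_start) - NDHF_IR_OVERHANG - max(100 // div, 40),
    )
    irb_feats = [rps19] + ir_rest
    all_feats = feats + [
        replace(f, copy_tag="IR-duplicated") for f in irb_feats
    ]
    for f in irb_feats:  # mirrored IRa copies
        parts = tuple(
            sorted(_mirror_ir_interval(p, lsc, ir, ssc, n) for p in f.parts)
        )
        all_feats.append(
            GeneFeature(
                name=f.name, kind=f.kind,
                strand="+" if f.strand == "-" else "-",
                parts=parts, copy_tag="IR-duplicated",
            )
        )
    all_feats.sort(key=lambda f: f.start)
    return all_feats, spacers


# ---------------------------------------------------------------------------
# Ancestor


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_BASE_P)


def simulate_ancestor(config: SimConfig):
    """Quadripartite ancestor with annotations, planted SSRs and planted
    diagnostic-site contexts.  Returns (plastome, spacer registry, ssr truth)."""
    rng = np.random.default_rng([config.seed, 0])
    lsc, ssc, ir = config.lsc_len, config.ssc_len, config.ir_len
    n = config.genome_length
    seq = np.empty(n, dtype=np.uint8)
    seq[: lsc + ir + ssc] = _random_seq(rng, lsc + ir + ssc)
    feats, spacers = build_annotations(config)
    ssr_truth: list[tuple[int, str, int]] = []
    for planted in config.planted_ssrs:
        mid = spacers[planted.spacer]
        run = planted.motif * planted.copies
        start = mid - len(run) // 2
        seq[start : start + len(run)] = np.frombuffer(run.encode(), dtype=np.uint8)
        # break the repeat on both sides so the planted run is maximal
        left = planted.motif[-1]
        right = planted.motif[0]
        seq[start - 1] = ord("C") if left in "AT" else ord("A")
        seq[start + len(run)] = ord("C") if right in "AT" else ord("A")
        ssr_truth.append((start, planted.motif, planted.copies))
    for snp in config.planted_snps:
        p = spacers[snp.spacer]
        ctx = snp.context5
        seq[p - len(ctx) : p] = np.frombuffer(ctx.encode(), dtype=np.uint8)
        seq[p] = ord(snp.ref_base)
    # IRa is the exact reverse complement of IRb
    irb = seq[lsc : lsc + ir]
    comp = np.empty(256, dtype=np.uint8)
    comp[ord("A")], comp[ord("C")], comp[ord("G")], comp[ord("T")] = (
        ord("T"), ord("G"), ord("C"), ord("A"),
    )
    seq[lsc + ir + ssc :] = comp[irb][::-1]
    # break inverted-repeat extension at the segment boundaries so that the
    # maximal exact IR pair is exactly the constructed one
    if seq[lsc - 1] == comp[seq[0]]:
        seq[lsc - 1] = _BASES[(int(np.argmax(_BASES == seq[lsc - 1])) + 1) % 4]
    if seq[lsc + ir] == comp[seq[lsc + ir + ssc - 1]]:
        seq[lsc + ir] = comp[seq[lsc + ir]]
        if seq[lsc + ir] == comp[seq[lsc + ir + ssc - 1]]:
            seq[lsc + ir] = _BASES[(int(np.argmax(_BASES == seq[lsc + ir])) + 1) % 4]
    genome = Plastome(
        id="REF", species="reference", sequence=seq.tobytes().decode()
    ).with_annotations(feats)
    return genome, spacers, ssr_truth


# ---------------------------------------------------------------------------
# Evolution


class _Reserver:
    """Non-overlapping interval bookkeeping for mutation placement."""

    def __init__(self):
        self.intervals: list[tuple[int, int]] = []

    def overlaps(self, a: int, b: int) -> bool:
        import bisect

        i = bisect.bisect_left(self.intervals, (a, a))
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(self.intervals):
                s, e = self.intervals[j]
                if s < b and a < e:
                    return True
        return False

    def reserve(self, a: int, b: int) -> None:
        import bisect

        bisect.insort(self.intervals, (a, b))


def _branch_paths(tree: BranchSpec) -> dict[str, list[BranchSpec]]:
    """Leaf name -> list of branches (root..leaf, root excluded)."""
    paths: dict[str, list[BranchSpec]] = {}

    def walk(node: BranchSpec, acc: list[BranchSpec]):
        acc2 = acc + ([node] if node.name != "root" else [])
        if not node.children:
            paths[node.name] = acc2
        for c in node.children:
            walk(c, acc2)

    walk(tree, [])
    return paths


def _tree_newick(tree: BranchSpec) -> str:
    def fmt(node: BranchSpec) -> str:
        if not node.children:
            if node.samples <= 1:
                return f"{node.name}_1"
            inner = ",".join(f"{node.name}_{i+1}" for i in range(node.samples))
            return f"({inner})"
        return "(" + ",".join(fmt(c) for c in node.children) + ")"

    return fmt(tree) + ";"


def _smallest_cover(tree: BranchSpec, carriers: set[str]) -> BranchSpec | None:
    """The branch whose leaf set is exactly ``carriers``, if one exists."""
    def walk(node: BranchSpec):
        names = {l.name for l in node.leaves()}
        if names == carriers and node.name != "root":
            return node
        for c in node.children:
            hit = walk(c)
            if hit is not None:
                return hit
        return None

    return walk(tree)


def evolve(ancestor: Plastome, config: SimConfig, spacers: dict[str, int]):
    """Evolve samples along the species tree; returns (genomes, groups, truth
    fields).  Every event is recorded normalized against the ancestor."""
    rng = np.random.default_rng([config.seed, 1])
    refseq = ancestor.sequence
    n = len(refseq)
    lsc, ssc, ir = config.lsc_len, config.ssc_len, config.ir_len
    tree = config.tree()
    reserver = _Reserver()
    # forbidden zones: planted SSRs (+ flanks) and diagnostic neighborhoods
    for sp in config.planted_ssrs:
        mid = spacers[sp.spacer]
        half = len(sp.motif) * sp.copies // 2 + 10
        reserver.reserve(mid - half, mid + half)
    diag_positions: list[int] = []
    for snp in config.planted_snps:
        diag_positions.append(spacers[snp.spacer])
    for ind in config.planted_indels:
        diag_positions.append(spacers[ind.spacer])
    for p in diag_positions:
        reserver.reserve(p - config.diag_flank, p + config.diag_flank)
    # keep the IR-boundary flank bases intact so detected segment lengths
    # stay exactly the configured ones in every sample
    for a, b in ((0, 2), (lsc - 2, lsc), (lsc + ir, lsc + ir + 2),
                 (lsc + ir + ssc - 2, lsc + ir + ssc), (n - 2, n)):
        reserver.reserve(a, b)

    if config.allow_ir_mutations:
        allowed = [(0, lsc), (lsc, lsc + ir), (lsc + ir, lsc + ir + ssc)]
    else:
        allowed = [(0, lsc), (lsc + ir, lsc + ir + ssc)]
    allowed_starts = np.array([a for a, _ in allowed])
    allowed_lens = np.array([b - a for a, b in allowed])
    total_allowed = int(allowed_lens.sum())
    cum_lens = np.cumsum(allowed_lens)

    def draw_position(span: int, buffer: int) -> int:
        for _ in range(10_000):
            u = int(rng.integers(0, total_allowed))
            seg = int(np.searchsorted(cum_lens, u, side="right"))
            p = int(allowed_starts[seg] + u - (cum_lens[seg] - allowed_lens[seg]))
            if p < 20 or p + span > n - 20:
                continue
            if not reserver.overlaps(p - buffer, p + span + buffer):
                return p
        raise RuntimeError("mutation budget exceeds available sites")

    def random_insert(length: int) -> str:
        return _random_seq(rng, length).tobytes().decode()

    def make_snp() -> TruthVariant:
        p = draw_position(1, 3)
        ref_b = refseq[p]
        w = config.ts_tv_weight
        alts = [_TRANSITION[ref_b]] + [b for b in "ACGT" if b != ref_b and b != _TRANSITION[ref_b]]
        probs = np.array([w, 1.0, 1.0])
        alt = alts[int(rng.choice(3, p=probs / probs.sum()))]
        reserver.reserve(p - 2, p + 3)
        return TruthVariant("SNP", p, ref_b, alt)

    def make_indel(fixed_len: int | None = None) -> TruthVariant:
        length = fixed_len if fixed_len is not None else int(rng.geometric(1.0 / config.indel_mean_len))
        insertion = fixed_len is not None or bool(rng.integers(0, 2))
        p = draw_position(length + 2, 18)
        if insertion:
            raw = (p, refseq[p], refseq[p] + random_insert(length))
        else:
            raw = (p, refseq[p : p + length + 1], refseq[p])
        pos, r, a = normalize_variant(refseq, *raw)
        reserver.reserve(pos - 2, p + length + 3)
        return TruthVariant("InDel", pos, r, a)

    # planted diagnostic events, assigned to the covering branch when the
    # carrier set is a clade, else to each carrier's terminal branch
    branch_events: dict[str, list[TruthVariant]] = {}
    deductions: dict[str, dict[str, int]] = {}
    diagnostic_snps: list[dict] = []
    diagnostic_indels: list[dict] = []
    leaf_names = [l.name for l in tree.leaves()]
    for snp in config.planted_snps:
        p = spacers[snp.spacer]
        ref_b = refseq[p]
        assert ref_b == snp.ref_base
        by_allele: dict[str, list[str]] = {}
        for grp, allele in snp.allele_by_group:
            by_allele.setdefault(allele, []).append(grp)
        allele_by_group = dict(snp.allele_by_group)
        for allele, grps in by_allele.items():
            ev = TruthVariant("SNP", p, ref_b, allele)
            clade = _smallest_cover(tree, set(grps))
            targets = [clade.name] if clade is not None else grps
            for t in targets:
                branch_events.setdefault(t, []).append(ev)
                deductions.setdefault(t, {}).setdefault("snps", 0)
                deductions[t]["snps"] += 1
        diagnostic_snps.append(
            {"pos": p, "ref": ref_b, "allele_by_group": allele_by_group,
             "spacer": snp.spacer}
        )
    for ind in config.planted_indels:
        p = spacers[ind.spacer]
        by_len: dict[int, list[str]] = {}
        for grp, length in ind.insert_len_by_group:
            by_len.setdefault(length, []).append(grp)
        alleles: dict[str, str] = {}
        for length, grps in by_len.items():
            ins = random_insert(length)
            pos, r, a = normalize_variant(refseq, p, refseq[p], refseq[p] + ins)
            ev = TruthVariant("InDel", pos, r, a)
            clade = _smallest_cover(tree, set(grps))
            targets = [clade.name] if clade is not None else grps
            for t in targets:
                branch_events.setdefault(t, []).append(ev)
                deductions.setdefault(t, {}).setdefault("indels", 0)
                deductions[t]["indels"] += 1
            for g in grps:
                alleles[g] = a
        diagnostic_indels.append(
            {"pos": p, "spacer": ind.spacer,
             "insert_len_by_group": dict(ind.insert_len_by_group)}
        )

    # random events per branch (deterministic traversal order)
    def visit(node: BranchSpec):
        if node.name != "root":
            ded = deductions.get(node.name, {})
            n_snps = max(node.snps - ded.get("snps", 0), 0)
            n_indels = max(node.indels - ded.get("indels", 0) - len(node.fixed_insertions), 0)
            evs = branch_events.setdefault(node.name, [])
            for _ in range(n_snps):
                evs.append(make_snp())
            for L in node.fixed_insertions:
                evs.append(make_indel(L))
            for _ in range(n_indels):
                evs.append(make_indel())
        for c in node.children:
            visit(c)

    visit(tree)

    paths = _branch_paths(tree)
    genomes: list[Plastome] = []
    mapping: dict[str, str] = {}
    per_sample: dict[str, list[TruthVariant]] = {}
    private = dict(config.private_budgets)
    for leaf in tree.leaves():
        shared = [ev for b in paths[leaf.name] for ev in branch_events.get(b.name, [])]
        for i in range(max(leaf.samples, 1)):
            sid = f"{leaf.name}_{i+1}"
            events = list(shared)
            psnp, pindel = private.get(leaf.name, (0, 0))
            for _ in range(psnp):
                events.append(make_snp())
            for _ in range(pindel):
                events.append(make_indel())
            events.sort(key=lambda e: e.pos)
            # mirrored IR SNPs under concerted evolution
            applied = list(events)
            if config.allow_ir_mutations and config.mirror_ir:
                for ev in events:
                    if ev.kind == "SNP" and lsc <= ev.pos < lsc + ir:
                        q = n - 1 - (ev.pos - lsc)
                        applied.append(
                            TruthVariant("SNP", q, _COMP[ev.ref], _COMP[ev.alt])
                        )
                applied.sort(key=lambda e: e.pos)
            seq = refseq
            for ev in sorted(applied, key=lambda e: e.pos, reverse=True):
                assert seq[ev.pos : ev.pos + len(ev.ref)] == ev.ref, (sid, ev)
                seq = seq[: ev.pos] + ev.alt + seq[ev.pos + len(ev.ref) :]
            genomes.append(Plastome(id=sid, species=leaf.name, sequence=seq))
            mapping[sid] = leaf.name
            per_sample[sid] = applied
    groups = GroupMap(mapping=mapping, group_order=leaf_names)
    return genomes, groups, per_sample, diagnostic_snps, diagnostic_indels


def simulate(config: SimConfig) -> SimulationResult:
    """Full simulation: ancestor + evolved genome set + ground truth."""
    ancestor, spacers, ssr_truth = simulate_ancestor(config)
    genomes, groups, per_sample, diag_snps, diag_indels = evolve(
        ancestor, config, spacers
    )
    truth = SyntheticTruth(
        per_sample=per_sample,
        planted_ssrs=ssr_truth,
        diagnostic_snps=diag_snps,
        diagnostic_indels=diag_indels,
        tree_newick=_tree_newick(config.tree()),
    )
    return SimulationResult(
        reference=ancestor, genomes=genomes, groups=groups, truth=truth, config=config
    )


def tiny_config(seed: int, samples_per_species: int = 1, **overrides) -> SimConfig:
    """A ~24 kb desk-scale configuration for fast scale-free tests.

    Segment lengths, gene lengths and branch budgets are shrunk about
    eightfold/fourfold; the quadripartite architecture, planted features and
    tree shape are unchanged.
    """
    kwargs = dict(
        seed=seed,
        lsc_len=15_000,
        ssc_len=3_600,
        ir_len=2_800,
        gene_scale_div=8,
        samples_per_species=samples_per_species,
        species_tree=default_species_tree(samples_per_species, budget_scale=0.25),
        diag_flank=160,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
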