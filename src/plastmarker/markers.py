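"""InDel and dCAPS marker design with in-silico PCR and restriction digestion.

An *InDel marker* is a primer pair flanking a species-diagnostic
insertion/deletion: the allele-specific amplicon sizes differ by the InDel
length and are resolvable on agarose.  A *dCAPS marker* converts a
species-diagnostic SNP into a fragment-length difference: a primer ending
one base before the SNP carries up to one introduced mismatch so that a
restriction-enzyme recognition site is completed by exactly one SNP allele;
after PCR and digestion, only that allele's product is cut.

Primer composition rules (length 18-26, GC 30-70 %, Wallace-rule Tm
2(A+T)+4(G+C) in 50-68 degC, homopolymer <= 5) are applied to conventional
flanking primers; the dCAPS mismatch primer is position-constrained (its 3'
terminus is fixed one base before the SNP and must match the template), so
only its length is constrained.  Amplicon sizes, not thermodynamics, are the
designed-for quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .comparative import DiagnosticVariant, MultipleAlignment, partition_category
from .io_formats import GroupMap, Plastome, revcomp

__all__ = [
    "Primer",
    "EnzymeSpec",
    "ENZYMES",
    "Amplicon",
    "MarkerConfig",
    "IndelMarker",
    "DCAPSDesign",
    "DesignFailure",
    "ValidationResult",
    "AmbiguousAmpliconError",
    "insilico_pcr",
    "digest",
    "design_indel_markers",
    "design_dcaps",
    "validate_marker",
    "conserved_positions",
    "wallace_tm",
]


class AmbiguousAmpliconError(ValueError):
    """Multiple candidate products of equal minimal size."""


@dataclass(frozen=True)
class Primer:
    """A primer written 5'->3'."""

    sequence: str
    name: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EnzymeSpec:
    """Restriction enzyme: recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        if not 4 <= len(self.site) <= 6:
            raise ValueError(f"recognition site of {self.name} must be 4-6 bp")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"cut offset of {self.name} outside the site")

    @property
    def palindromic(self) -> bool:
        return revcomp(self.site) == self.site


ENZYMES: dict[str, EnzymeSpec] = {
    "TaqI": EnzymeSpec("TaqI", "TCGA", 1),
    "XbaI": EnzymeSpec("XbaI", "TCTAGA", 1),
}


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product (primer bases incorporated)."""

    template_id: str
    start: int  # binding start of the forward primer on the template
    end: int    # may exceed template length when the product wraps the origin
    sequence: str

    @property
    def size(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MarkerConfig:
    product_min: int = 100
    product_max: int = 300
    min_size_diff: int = 10  # gel resolvability on 2-3% agarose
    primer_min: int = 18
    primer_max: int = 26
    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 50.0
    tm_max: float = 68.0
    homopolymer_max: int = 5
    pcr_max_mismatch: int = 2
    max_introduced: int = 1


@dataclass(frozen=True)
class IndelMarker:
    id: str
    fwd: Primer
    rev: Primer
    locus_label: str | None
    ref_interval: tuple[int, int]
    size_by_group: dict[str, int] = field(hash=False, compare=False)
    category: str = ""


@dataclass(frozen=True)
class DCAPSDesign:
    id: str
    fwd: Primer
    rev: Primer
    dcaps_side: str  # which primer carries the SNP-adjacent 3' end: fwd|rev
    snp_pos: int
    enzyme: EnzymeSpec
    cut_allele: str
    introduced_mismatches: int
    locus_label: str | None
    size_by_allele: dict[str, int] = field(hash=False, compare=False)
    fragments_by_allele: dict[str, tuple[int, ...]] = field(hash=False, compare=False)
    is_caps: bool = False  # zero introduced mismatches: plain CAPS

    @property
    def category(self) -> str:
        return "CAPS" if self.is_caps else "dCAPS"


@dataclass(frozen=True)
class DesignFailure:
    locus: str
    reason: str


@dataclass(frozen=True)
class ValidationResult:
    verdict: bool
    pattern_by_sample: dict[str, tuple[int, ...]] = field(hash=False, compare=False)
    reason: str = ""


# ---------------------------------------------------------------------------
# Primer arithmetic


def wallace_tm(seq: str) -> float:
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * (len(seq) - gc) + 4.0 * gc


def _gc_frac(seq: str) -> float:
    return sum(seq.count(b) for b in "GC") / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def primer_ok(seq: str, cfg: MarkerConfig) -> bool:
    return (
        cfg.primer_min <= len(seq) <= cfg.primer_max
        and cfg.gc_min <= _gc_frac(seq) <= cfg.gc_max
        and cfg.tm_min <= wallace_tm(seq) <= cfg.tm_max
        and _max_homopolymer(seq) <= cfg.homopolymer_max
        and "N" not in seq
    )


# ---------------------------------------------------------------------------
# In-silico PCR


def _binding_sites(template2: str, probe: str, max_mismatch: int, exact_idx: int,
                   limit: int) -> list[tuple[int, int]]:
    """(start, n_mismatch) of probe matches on template2[:limit+len(probe)].

    ``exact_idx`` is the probe index that must match exactly (the 3' terminus).
    """
    p = len(probe)
    t = np.frombuffer(template2.encode(), dtype=np.uint8)
    if t.size < p:
        return []
    win = np.lib.stride_tricks.sliding_window_view(t, p)
    q = np.frombuffer(probe.encode(), dtype=np.uint8)
    mism = (win != q).sum(axis=1)
    hits = np.flatnonzero((mism <= max_mismatch) & (win[:, exact_idx] == q[exact_idx]))
    return [(int(i), int(mism[i])) for i in hits if i < limit]


def insilico_pcr(
    fwd: Primer,
    rev: Primer,
    template: Plastome,
    max_mismatch: int = 2,
    max_product: int = 5000,
) -> Amplicon | None:
    """Predict the PCR product of a primer pair on a (circular) template.

    Binding requires an exact 3'-terminal base and at most ``max_mismatch``
    total mismatches per primer.  Returns the smallest correctly oriented
    product <= ``max_product`` with primer bases incorporated, ``None`` when
    either primer finds no site, and raises :class:`AmbiguousAmpliconError`
    when two distinct minimal products tie.
    """
    seq = template.sequence
    L = len(seq)
    ext = max_product if template.circular else 0
    seq2 = seq + seq[: min(ext, L)]
    f = fwd.sequence.upper()
    rc_r = revcomp(rev.sequence.upper())
    fwd_sites = _binding_sites(seq2, f, max_mismatch, len(f) - 1, L)
    rev_sites = _binding_sites(seq2, rc_r, max_mismatch, 0, L + ext - len(rc_r) + 1)
    if not fwd_sites or not rev_sites:
        return None
    candidates: list[tuple[int, int, int]] = []  # (size, i, j)
    for i, _ in fwd_sites:
        for j, _ in rev_sites:
            if j < i + len(f):
                continue
            size = j + len(rc_r) - i
            if size <= max_product:
                candidates.append((size, i, j))
    if not candidates:
        return None
    candidates.sort()
    best = candidates[0]
    ties = [
        c for c in candidates[1:]
        if c[0] == best[0] and (c[1] % L, c[2] % L) != (best[1] % L, best[2] % L)
    ]
    if ties:
        raise AmbiguousAmpliconError(
            f"{len(ties) + 1} products of {best[0]} bp on template {template.id}"
        )
    size, i, j = best
    product = f + seq2[i + len(f) : j] + rc_r
    return Amplicon(template_id=template.id, start=i, end=j + len(rc_r), sequence=product)


def digest(product: Amplicon | str, enzyme: EnzymeSpec) -> list[int]:
    """Ordered fragment sizes after cutting every recognition-site occurrence.

    Each site occurrence yields one cut, at the enzyme's top-strand offset
    within the site as found (the bottom-strand orientation is scanned too
    for non-palindromic sites).  Zero cuts return the whole product.
    """
    seq = product.sequence if isinstance(product, Amplicon) else product
    site = enzyme.site
    cuts: set[int] = set()
    start = 0
    while (k := seq.find(site, start)) != -1:
        cuts.add(k + enzyme.cut_offset)
        start = k + 1
    if not enzyme.palindromic:
        rc_site = revcomp(site)
        start = 0
        while (k := seq.find(rc_site, start)) != -1:
            cuts.add(k + len(site) - enzyme.cut_offset)
            start = k + 1
    bounds = [0] + sorted(c for c in cuts if 0 < c < len(seq)) + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# Conserved-flank detection


def conserved_positions(aln: MultipleAlignment) -> np.ndarray:
    """Boolean mask over reference positions safe to place a primer on.

    A position is conserved when every sample carries the reference base in
    its column and no sample has an insertion immediately around it.
    """
    mat = aln.matrix()
    ref_row = mat[aln.ids.index(aln.reference_id)]
    eq_all = (mat == ref_row[None, :]).all(axis=0)
    coords = aln.ref_coords
    ref_cols = coords >= 0
    n = int(coords.max()) + 1
    cons = np.zeros(n, dtype=bool)
    cons[coords[ref_cols]] = eq_all[ref_cols]
    next_ref = np.full(len(coords), n, dtype=np.int64)
    nxt = n
    for c in range(len(coords) - 1, -1, -1):
        if coords[c] >= 0:
            nxt = coords[c]
        next_ref[c] = nxt
    for c in np.flatnonzero(~ref_cols):
        r = int(next_ref[c])
        if r < n:
            cons[r] = False
        if r - 1 >= 0:
            cons[r - 1] = False
    return cons


def _clean(cons: np.ndarray, start: int, end: int) -> bool:
    return 0 <= start and end <= cons.size and bool(cons[start:end].all())


def _find_primer(
    refseq: str, cons: np.ndarray, cfg: MarkerConfig, side: str,
    anchor: int, scan: int = 120,
) -> tuple[int, int] | None:
    """First rule-passing conserved primer placement near ``anchor``.

    ``side='left'`` returns a forward primer ending at or before ``anchor``
    (interval (start, end) with end <= anchor); ``side='right'`` a reverse
    primer starting at or after ``anchor``.  Placements are scanned outward
    from the anchor, shortest primer first, deterministic.
    """
    for shift in range(scan):
        for plen in range(cfg.primer_min, cfg.primer_max + 1):
            if side == "left":
                end = anchor - shift
                start = end - plen
                if start < 0:
                    continue
                seq = refseq[start:end]
            else:
                start = anchor + shift
                end = start + plen
                if end > len(refseq):
                    continue
                seq = revcomp(refseq[start:end])
            if _clean(cons, start, end) and primer_ok(seq, cfg):
                return (start, end)
    return None


def _find_opposing_primer(
    refseq: str, cons: np.ndarray, cfg: MarkerConfig, start_f: int, min_start: int,
) -> tuple[int, int] | None:
    """Conserved reverse primer giving a product inside the size window.

    Scans right ends ascending (smallest product first); the primer interval
    must start at or after ``min_start`` (past the event/site tail).
    """
    lo = max(start_f + cfg.product_min, min_start + cfg.primer_min)
    hi = min(start_f + cfg.product_max, len(refseq))
    for end in range(lo, hi + 1):
        for plen in range(cfg.primer_min, cfg.primer_max + 1):
            start = end - plen
            if start < min_start:
                break
            seq = revcomp(refseq[start:end])
            if _clean(cons, start, end) and primer_ok(seq, cfg):
                return (start, end)
    return None


# ---------------------------------------------------------------------------
# InDel marker design


def _representatives(groups: GroupMap, genomes: list[Plastome]) -> dict[str, Plastome]:
    by_id = {g.id: g for g in genomes}
    reps = {}
    for grp in groups.group_order:
        for sid in groups.samples_in(grp):
            if sid in by_id:
                reps[grp] = by_id[sid]
                break
    return reps


def design_indel_markers(
    aln: MultipleAlignment,
    diagnostics: list[DiagnosticVariant],
    genomes: list[Plastome],
    groups: GroupMap,
    config: MarkerConfig | None = None,
) -> tuple[list[IndelMarker], list[DesignFailure]]:
    """One marker per qualifying diagnostic InDel with conserved flanks.

    Primers are placed in flanking sequence carrying no variant in any
    sample; expected product sizes per group come from in-silico PCR on one
    representative genome per group, and must show >= 2 distinct sizes
    separated by at least the resolvability threshold.
    """
    cfg = config or MarkerConfig()
    cons = conserved_positions(aln)
    reps = _representatives(groups, genomes)
    ref = next(g for g in genomes if g.id == aln.reference_id)
    refseq = ref.sequence
    markers: list[IndelMarker] = []
    failures: list[DesignFailure] = []
    idx = 0
    for diag in diagnostics:
        v = diag.variant
        if v.kind != "InDel":
            continue
        locus = v.locus_label or f"pos{v.ref_pos}"
        if v.indel_length < cfg.min_size_diff:
            failures.append(
                DesignFailure(locus, f"InDel of {v.indel_length} bp below "
                                     f"{cfg.min_size_diff} bp resolvability")
            )
            continue
        event_start = v.ref_pos  # anchor base, shared by all alleles
        event_end = v.ref_pos + len(v.ref_allele)
        fwd_iv = _find_primer(refseq, cons, cfg, "left", event_start + 1)
        rev_iv = None
        if fwd_iv is not None:
            rev_iv = _find_opposing_primer(refseq, cons, cfg, fwd_iv[0], event_end)
        if fwd_iv is None or rev_iv is None:
            failures.append(DesignFailure(locus, "no conserved rule-passing flank"))
            continue
        idx += 1
        fwd = Primer(refseq[fwd_iv[0] : fwd_iv[1]], name=f"Id{idx}F")
        rev = Primer(revcomp(refseq[rev_iv[0] : rev_iv[1]]), name=f"Id{idx}R")
        size_by_group: dict[str, int] = {}
        ok = True
        for grp, rep in reps.items():
            amp = insilico_pcr(fwd, rev, rep, max_mismatch=cfg.pcr_max_mismatch)
            if amp is None:
                failures.append(DesignFailure(locus, f"no amplification in group {grp}"))
                ok = False
                break
            size_by_group[grp] = amp.size
        if not ok:
            continue
        distinct = sorted(set(size_by_group.values()))
        if len(distinct) < 2 or min(
            b - a for a, b in zip(distinct, distinct[1:])
        ) < cfg.min_size_diff:
            failures.append(DesignFailure(locus, "group product sizes not resolvable"))
            continue
        cells: dict[int, list[str]] = {}
        for grp, s in size_by_group.items():
            cells.setdefault(s, []).append(grp)
        partition = tuple(tuple(sorted(c)) for c in sorted(cells.values(), key=lambda c: (len(c), c)))
        markers.append(
            IndelMarker(
                id=f"Id{idx}",
                fwd=fwd,
                rev=rev,
                locus_label=v.locus_label,
                ref_interval=(fwd_iv[0], rev_iv[1]),
                size_by_group=size_by_group,
                category=partition_category(partition),
            )
        )
    return markers, failures


# ---------------------------------------------------------------------------
# dCAPS design


def _site_overlaps_pos(seq: str, site: str, pos: int) -> bool:
    for s in range(max(0, pos - len(site) + 1), min(pos + 1, len(seq) - len(site) + 1)):
        if seq[s : s + len(site)] == site:
            return True
    return False


def design_dcaps(
    aln: MultipleAlignment,
    snp: DiagnosticVariant,
    genomes: list[Plastome],
    groups: GroupMap,
    enzymes: list[EnzymeSpec] | None = None,
    config: MarkerConfig | None = None,
) -> tuple[list[DCAPSDesign], list[DesignFailure]]:
    """dCAPS (or degenerate CAPS) designs for one diagnostic biallelic SNP.

    For every enzyme, strand and placement of the recognition site over the
    SNP, a primer ending one base before the SNP is given the introduced
    substitutions (never at its 3' terminus) that complete the site for
    exactly one allele; designs are verified by in-silico PCR and digestion
    on one representative genome per allele and emitted only when the two
    allele band patterns are resolvable.
    """
    cfg = config or MarkerConfig()
    enzymes = enzymes if enzymes is not None else [ENZYMES["TaqI"], ENZYMES["XbaI"]]
    v = snp.variant
    if v.kind != "SNP":
        raise ValueError("design_dcaps needs a SNP diagnostic")
    allele_values = sorted(set(snp.allele_by_group.values()))
    if len(allele_values) != 2:
        raise ValueError("design_dcaps needs a biallelic partition")
    cons = conserved_positions(aln)
    ref = next(g for g in genomes if g.id == aln.reference_id)
    n = len(ref.sequence)
    reps_by_allele: dict[str, Plastome] = {}
    by_id = {g.id: g for g in genomes}
    for grp, allele in snp.allele_by_group.items():
        if allele in reps_by_allele:
            continue
        for sid in groups.samples_in(grp):
            if sid in by_id:
                reps_by_allele[allele] = by_id[sid]
                break
    designs: list[DCAPSDesign] = []
    failures: list[DesignFailure] = []
    locus = v.locus_label or f"pos{v.ref_pos}"
    for enzyme in enzymes:
        site = enzyme.site
        Ls = len(site)
        emitted = False
        reasons: list[str] = []
        for strand in "+-":
            if strand == "+":
                view = ref.sequence
                p = v.ref_pos
                alleles = {a: a for a in allele_values}
                cons_v = cons
            else:
                view = revcomp(ref.sequence)
                p = n - 1 - v.ref_pos
                alleles = {a: revcomp(a) for a in allele_values}
                cons_v = cons[::-1]
            for s in range(p - Ls + 1, p + 1):
                if s < 0 or s + Ls > len(view):
                    continue
                k = p - s  # index of the SNP inside the site
                site_base = site[k]
                matching = [a for a, av in alleles.items() if av == site_base]
                if len(matching) != 1:
                    continue
                cut_allele = matching[0]
                tail = view[p + 1 : s + Ls]
                if tail != site[k + 1 :]:
                    reasons.append(f"{strand}{s}: template tail breaks the site")
                    continue
                if not _clean(cons_v, p + 1, s + Ls):
                    reasons.append(f"{strand}{s}: variant under the site tail")
                    continue
                head = view[s:p]
                introduced = [i for i in range(k) if head[i] != site[i]]
                if len(introduced) > cfg.max_introduced:
                    continue
                if k >= 1 and (k - 1) in introduced:
                    continue  # never mismatch the 3'-terminal base
                # longest feasible primer: the introduced mismatch destabilizes
                # annealing, so dCAPS primers are kept at maximal length
                plen = min(cfg.primer_max, p)
                if plen < k or plen < min(cfg.primer_min, p):
                    reasons.append(f"{strand}{s}: primer length infeasible")
                    continue
                start_f = p - plen
                if not _clean(cons_v, start_f, p):
                    reasons.append(f"{strand}{s}: variant under the dCAPS primer")
                    continue
                primer_chars = list(view[start_f:p])
                for i in range(k):
                    primer_chars[plen - k + i] = site[i]
                dcaps_primer = "".join(primer_chars)
                rev_iv = _find_opposing_primer(
                    view, cons_v, cfg, start_f, max(s + Ls, p + 1)
                )
                if rev_iv is None:
                    reasons.append(f"{strand}{s}: no opposing primer in product window")
                    continue
                opp_primer = revcomp(view[rev_iv[0] : rev_iv[1]])
                if strand == "+":
                    fwd, rev = Primer(dcaps_primer), Primer(opp_primer)
                    dcaps_side = "fwd"
                else:
                    fwd, rev = Primer(opp_primer), Primer(dcaps_primer)
                    dcaps_side = "rev"
                size_by_allele: dict[str, int] = {}
                frags_by_allele: dict[str, tuple[int, ...]] = {}
                overlap_by_allele: dict[str, bool] = {}
                ok = True
                for allele, rep in reps_by_allele.items():
                    try:
                        amp = insilico_pcr(fwd, rev, rep, max_mismatch=cfg.pcr_max_mismatch)
                    except AmbiguousAmpliconError:
                        amp = None
                    if amp is None:
                        ok = False
                        reasons.append(f"{strand}{s}: no amplification for allele {allele}")
                        break
                    frags = digest(amp, enzyme)
                    assert sum(frags) == amp.size
                    size_by_allele[allele] = amp.size
                    frags_by_allele[allele] = tuple(frags)
                    snp_in_product = plen if strand == "+" else amp.size - 1 - plen
                    prod_seq = amp.sequence if strand == "+" else revcomp(amp.sequence)
                    overlap_by_allele[allele] = _site_overlaps_pos(
                        amp.sequence if strand == "+" else prod_seq,
                        site,
                        plen,
                    )
                if not ok:
                    continue
                if sum(overlap_by_allele.values()) != 1:
                    reasons.append(f"{strand}{s}: site not allele-specific")
                    continue
                patterns = list(frags_by_allele.values())
                if len(set(patterns)) < 2 or abs(
                    max(patterns[0]) - max(patterns[1])
                ) < cfg.min_size_diff:
                    reasons.append(f"{strand}{s}: band patterns not resolvable")
                    continue
                designs.append(
                    DCAPSDesign(
                        id=f"d{enzyme.name}_{strand}{s}",
                        fwd=fwd,
                        rev=rev,
                        dcaps_side=dcaps_side,
                        snp_pos=v.ref_pos,
                        enzyme=enzyme,
                        cut_allele=cut_allele,
                        introduced_mismatches=len(introduced),
                        locus_label=v.locus_label,
                        size_by_allele=size_by_allele,
                        fragments_by_allele=frags_by_allele,
                        is_caps=len(introduced) == 0,
                    )
                )
                emitted = True
        if not emitted:
            failures.append(
                DesignFailure(locus, f"{enzyme.name}: " + ("; ".join(reasons[:4]) or
                                                          "no placement matched an allele"))
            )
    return designs, failures


# ---------------------------------------------------------------------------
# Validation


def validate_marker(
    marker: IndelMarker | DCAPSDesign,
    genomes: list[Plastome],
    groups: GroupMap,
    config: MarkerConfig | None = None,
) -> ValidationResult:
    """Predict band sizes per sample; verdict is True iff the pattern is
    constant within groups and distinct between at least two groups."""
    cfg = config or MarkerConfig()
    patterns: dict[str, tuple[int, ...]] = {}
    for g in genomes:
        if g.id not in groups.mapping:
            continue
        try:
            amp = insilico_pcr(marker.fwd, marker.rev, g, max_mismatch=cfg.pcr_max_mismatch)
        except AmbiguousAmpliconError:
            amp = None
        if amp is None:
            return ValidationResult(
                verdict=False, pattern_by_sample=patterns,
                reason=f"no amplification in sample {g.id}",
            )
        if isinstance(marker, DCAPSDesign):
            patterns[g.id] = tuple(sorted(digest(amp, marker.enzyme)))
        else:
            patterns[g.id] = (amp.size,)
    by_group: dict[str, set[tuple[int, ...]]] = {}
    for sid, pat in patterns.items():
        by_group.setdefault(groups.group_of(sid), set()).add(pat)
    for grp, pats in by_group.items():
        if len(pats) > 1:
            return ValidationResult(
                verdict=False, pattern_by_sample=patterns,
                reason=f"pattern varies within group {grp}",
            )
    distinct = {next(iter(p)) for p in by_group.values()}
    if len(distinct) < 2:
        return ValidationResult(
            verdict=False, pattern_by_sample=patterns,
            reason="no group separated by the marker",
        )
    return ValidationResult(verdict=True, pattern_by_sample=patterns)
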