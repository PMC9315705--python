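"""Collinear multiple alignment, variant calling and species diagnostics.

Near-identical plastomes (no rearrangements, sparse SNPs/InDels) are aligned
with a center-star strategy: each genome is aligned pairwise to the reference
with the banded global aligner and the pairwise alignments are merged on
reference coordinates.  Variants are then read off alignment columns: one SNP
per polymorphic substitution column, consecutive gap columns in a sample
merged into a single InDel event, left-aligned and parsimony-normalized as in
VCF.  Sites containing N are treated as missing and excluded.

A *diagnostic* variant is fixed within every species group and differs
between at least two groups; the partition of groups it induces determines
its marker category (three-way / two-vs-rest / one-vs-rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import DEFAULT_BAND, CollinearityError, banded_align
from .io_formats import GeneFeature, GroupMap, Plastome

__all__ = [
    "MultipleAlignment",
    "VariantRecord",
    "DiagnosticVariant",
    "align_plastomes",
    "call_variants",
    "normalize_variant",
    "classify_regions",
    "diagnostic_variants",
    "region_identity",
    "partition_category",
]


@dataclass
class MultipleAlignment:
    """Equal-length rows over {A,C,G,T,N,-} with a column->reference map.

    ``ref_coords[c]`` is the reference coordinate of column ``c`` for columns
    carrying a reference base, and -1 for insertion columns (columns where the
    reference row is gapped).
    """

    ids: list[str]
    rows: list[str]
    reference_id: str
    ref_coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal alignment row lengths: {sorted(lengths)}")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} absent from alignment")

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sample_id: str) -> str:
        return self.rows[self.ids.index(sample_id)]

    def degapped(self, sample_id: str) -> str:
        return self.row(sample_id).replace("-", "")

    def matrix(self) -> np.ndarray:
        return np.vstack(
            [np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows]
        )

    @classmethod
    def from_aligned(cls, ids: list[str], rows: list[str], reference_id: str
                     ) -> "MultipleAlignment":
        ref_row = rows[ids.index(reference_id)]
        coords = np.full(len(ref_row), -1, dtype=np.int64)
        r = 0
        for c, ch in enumerate(ref_row):
            if ch != "-":
                coords[c] = r
                r += 1
        return cls(ids=ids, rows=rows, reference_id=reference_id, ref_coords=coords)


def _pairwise_to_events(ref_aln: str, smp_aln: str):
    """Per-reference-position substitution array and insertion map."""
    n = sum(1 for ch in ref_aln if ch != "-")
    sub = [""] * n
    ins: dict[int, str] = {}
    r = 0
    for x, y in zip(ref_aln, smp_aln):
        if x != "-":
            sub[r] = y
            r += 1
        elif y != "-":  # gap-gap columns (other samples' insertions) carry nothing
            ins[r] = ins.get(r, "") + y
    return sub, ins


def align_plastomes(
    genomes: list[Plastome],
    reference_id: str,
    band: int = DEFAULT_BAND,
    max_length_frac: float = 0.01,
) -> MultipleAlignment:
    """Center-star multiple alignment of canonicalized plastomes.

    All genomes are aligned pairwise to the reference and merged on reference
    coordinates; shared insertions (identical strings at one site) end up in
    shared columns.  Raises :class:`CollinearityError` when lengths differ by
    more than ``max_length_frac`` of the reference length.
    """
    by_id = {g.id: g for g in genomes}
    if reference_id not in by_id:
        raise ValueError(f"reference id {reference_id!r} not among inputs")
    ref = by_id[reference_id]
    n = len(ref.sequence)
    for g in genomes:
        if abs(len(g.sequence) - n) >= max_length_frac * n:
            raise CollinearityError(
                f"genome {g.id} length {len(g.sequence)} differs from reference "
                f"by >= {max_length_frac:.0%}; supply a precomputed alignment"
            )
    subs: dict[str, list[str]] = {}
    ins_maps: dict[str, dict[int, str]] = {}
    for g in genomes:
        if g.id == reference_id:
            continue
        ra, sa, _ = banded_align(ref.sequence, g.sequence, band=band)
        subs[g.id], ins_maps[g.id] = _pairwise_to_events(ra, sa)
    ins_len = np.zeros(n + 1, dtype=np.int64)
    for m in ins_maps.values():
        for r, s in m.items():
            ins_len[r] = max(ins_len[r], len(s))
    ids = [g.id for g in genomes]
    rows: list[str] = []
    coords_parts: list[np.ndarray] = []
    for sid in ids:
        out: list[str] = []
        if sid == reference_id:
            for r in range(n + 1):
                out.append("-" * ins_len[r])
                if r < n:
                    out.append(ref.sequence[r])
            rows.append("".join(out))
        else:
            sub, ins = subs[sid], ins_maps[sid]
            for r in range(n + 1):
                s = ins.get(r, "")
                out.append(s + "-" * (ins_len[r] - len(s)))
                if r < n:
                    out.append(sub[r])
            rows.append("".join(out))
    coords = np.empty(len(rows[0]), dtype=np.int64)
    c = 0
    for r in range(n + 1):
        coords[c : c + ins_len[r]] = -1
        c += ins_len[r]
        if r < n:
            coords[c] = r
            c += 1
    aln = MultipleAlignment(ids=ids, rows=rows, reference_id=reference_id, ref_coords=coords)
    for g in genomes:  # de-gap round-trip invariant
        assert aln.degapped(g.id) == g.sequence
    return aln


# ---------------------------------------------------------------------------
# Variant records


@dataclass(frozen=True)
class VariantRecord:
    """A SNP or InDel against the reference, VCF-style left-aligned.

    ``ref_pos`` is the 0-based internal reference coordinate (for InDels the
    anchor-base position).  ``calls`` maps every confidently-called sample to
    its allele string (reference allele for non-carriers).
    """

    kind: str  # SNP | InDel
    ref_pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: dict[str, str] = field(default_factory=dict, hash=False, compare=False)
    region: str | None = None
    locus_label: str | None = None

    @property
    def indel_length(self) -> int:
        return max(abs(len(a) - len(self.ref_allele)) for a in self.alt_alleles)

    def key(self) -> tuple:
        return (self.kind, self.ref_pos, self.ref_allele, self.alt_alleles)


@dataclass(frozen=True)
class DiagnosticVariant:
    """A variant fixed within groups, with the group partition it induces."""

    variant: VariantRecord
    allele_by_group: dict[str, str] = field(hash=False, compare=False)
    partition: tuple[tuple[str, ...], ...] = ()
    category: str = ""


def normalize_variant(refseq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim a (pos, ref, alt) event (VCF semantics)."""
    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        last = ref[-1]
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 0:  # cannot shift past the origin; keep the right anchor
                ref, alt = ref + last, alt + last
                break
            pos -= 1
            base = refseq[pos]
            ref, alt = base + ref, base + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _indel_record(refseq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    return normalize_variant(refseq, pos, ref, alt)


def call_variants(aln: MultipleAlignment, reference_id: str | None = None
                  ) -> list[VariantRecord]:
    """Read SNPs and InDels off alignment columns for every non-reference sample."""
    reference_id = reference_id or aln.reference_id
    if reference_id not in aln.ids:
        raise ValueError(f"reference id {reference_id!r} absent from alignment")
    ref_row = aln.row(reference_id)
    refseq = ref_row.replace("-", "")
    per_site: dict[tuple, dict[str, str]] = {}

    def record_event(key: tuple, sample: str, allele: str):
        per_site.setdefault(key, {})[sample] = allele

    sample_ids = [sid for sid in aln.ids if sid != reference_id]
    n_missing: dict[tuple, set[str]] = {}
    for sid in sample_ids:
        row = aln.row(sid)
        sub, ins = _pairwise_to_events(ref_row, row)
        # ref coordinates of this sample's aligned bases
        r = 0
        # SNPs and deletions from the substitution array
        del_start = None
        for r, (rbase, sbase) in enumerate(zip(refseq, sub)):
            if sbase == "-":
                if del_start is None:
                    del_start = r
                continue
            if del_start is not None:
                p0 = del_start
                ref_a = refseq[max(p0 - 1, 0) : r]
                alt_a = refseq[max(p0 - 1, 0)] if p0 > 0 else refseq[r]
                if p0 == 0:
                    ref_a = refseq[0:r] + refseq[r]
                    alt_a = refseq[r]
                if "N" not in ref_a:
                    pos, rr, aa = _indel_record(refseq, max(p0 - 1, 0), ref_a, alt_a)
                    record_event(("InDel", pos, rr, aa), sid, aa)
                del_start = None
            if sbase != rbase:
                if sbase == "N" or rbase == "N":
                    n_missing.setdefault(("pos", r), set()).add(sid)
                else:
                    record_event(("SNP", r, rbase, sbase), sid, sbase)
        if del_start is not None:  # deletion running to the end
            p0 = del_start
            ref_a = refseq[p0 - 1 :] if p0 > 0 else refseq
            alt_a = refseq[p0 - 1] if p0 > 0 else refseq[-1]
            if "N" not in ref_a:
                pos, rr, aa = _indel_record(refseq, max(p0 - 1, 0), ref_a, alt_a)
                record_event(("InDel", pos, rr, aa), sid, aa)
        # insertions
        for r, s in ins.items():
            if "N" in s:
                continue
            if r > 0:
                pos, ref_a, alt_a = r - 1, refseq[r - 1], refseq[r - 1] + s
            else:
                pos, ref_a, alt_a = 0, refseq[0], s + refseq[0]
            pos, rr, aa = _indel_record(refseq, pos, ref_a, alt_a)
            record_event(("InDel", pos, rr, aa), sid, aa)

    # Merge per-sample events into multi-allelic records keyed by site.
    grouped: dict[tuple, dict[str, str]] = {}
    for (kind, pos, ref_a, alt_a), calls in per_site.items():
        site = (kind, pos, ref_a)
        grouped.setdefault(site, {}).update(calls)
    records: list[VariantRecord] = []
    for (kind, pos, ref_a), calls in sorted(grouped.items(), key=lambda kv: kv[0][1]):
        alts = tuple(sorted(set(calls.values())))
        full_calls = dict(calls)
        for sid in sample_ids:
            if sid not in full_calls:
                full_calls[sid] = ref_a
        full_calls[reference_id] = ref_a
        records.append(
            VariantRecord(
                kind=kind, ref_pos=pos, ref_allele=ref_a, alt_alleles=alts,
                calls=full_calls,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Region classification


def _flanking_label(genes: list[GeneFeature], pos: int, n: int) -> str:
    """'upstreamGene-downstreamGene' label for an intergenic position."""
    prev_g = None
    prev_d = None
    next_g = None
    next_d = None
    for g in genes:
        d_prev = (pos - g.end) % n
        d_next = (g.start - pos) % n
        if prev_d is None or d_prev < prev_d:
            prev_g, prev_d = g, d_prev
        if next_d is None or d_next < next_d:
            next_g, next_d = g, d_next
    return f"{prev_g.name}-{next_g.name}"


def classify_position(reference: Plastome, pos: int) -> tuple[str, str]:
    """(region, locus_label) of a reference position.

    Region is CDS/tRNA/rRNA when inside an exonic part, intron when inside a
    gene's intron gap, else intergenic with an 'upstream-downstream' label in
    reference orientation.
    """
    if not reference.annotations:
        raise ValueError(f"reference {reference.id} is unannotated")
    intron_hit = None
    for feat in reference.annotations:
        if feat.contains(pos):
            return feat.kind, feat.name
        if intron_hit is None and feat.in_intron(pos):
            intron_hit = feat
    if intron_hit is not None:
        return "intron", intron_hit.name
    label = _flanking_label(reference.annotations, pos, len(reference.sequence))
    return "intergenic", label


def classify_regions(variants: list[VariantRecord], reference: Plastome
                     ) -> list[VariantRecord]:
    """Attach region class and locus label to every variant."""
    out = []
    for v in variants:
        pos = v.ref_pos if v.kind == "SNP" else min(v.ref_pos + 1, len(reference.sequence) - 1)
        region, label = classify_position(reference, pos)
        out.append(replace(v, region=region, locus_label=label))
    return out


# ---------------------------------------------------------------------------
# Diagnostics


def partition_category(partition: tuple[tuple[str, ...], ...]) -> str:
    if len(partition) >= 3:
        return "three-way"
    sizes = sorted(len(cell) for cell in partition)
    k = sizes[0]
    return {1: "one-vs-rest", 2: "two-vs-rest"}.get(k, f"{k}-vs-rest")


def diagnostic_variants(variants: list[VariantRecord], groups: GroupMap
                        ) -> list[DiagnosticVariant]:
    """Variants fixed within each group and differing between >= 2 groups."""
    for g in groups.group_order:
        if not groups.samples_in(g):
            raise ValueError(f"group {g!r} has no samples")
    out: list[DiagnosticVariant] = []
    for v in variants:
        allele_by_group: dict[str, str] = {}
        ok = True
        for g in groups.group_order:
            alleles = set()
            for sid in groups.samples_in(g):
                a = v.calls.get(sid)
                if a is None:
                    ok = False
                    break
                alleles.add(a)
            if not ok or len(alleles) != 1:
                ok = False
                break
            allele_by_group[g] = alleles.pop()
        if not ok:
            continue
        cells: dict[str, list[str]] = {}
        for g, a in allele_by_group.items():
            cells.setdefault(a, []).append(g)
        if len(cells) < 2:
            continue
        partition = tuple(
            tuple(sorted(cell)) for cell in sorted(cells.values(), key=lambda c: (len(c), c))
        )
        out.append(
            DiagnosticVariant(
                variant=v,
                allele_by_group=allele_by_group,
                partition=partition,
                category=partition_category(partition),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-class identity


def region_identity(aln: MultipleAlignment, reference: Plastome) -> dict[str, tuple[float, float]]:
    """Mean pairwise percent identity (+/- sd over pairs) per feature class.

    Classes are tRNA, rRNA, exon (CDS), intron and intergenic; a gap in one
    row of a column counts as a difference, a gap in both rows as identity.
    Insertion columns inherit the class of the preceding reference position.
    """
    if not reference.annotations:
        raise ValueError(f"reference {reference.id} is unannotated")
    n = len(reference.sequence)
    classes = np.full(n, 4, dtype=np.int8)  # 0 tRNA, 1 rRNA, 2 exon, 3 intron, 4 intergenic
    code = {"tRNA": 0, "rRNA": 1, "CDS": 2}
    for feat in reference.annotations:
        classes[feat.start : feat.end] = np.minimum(classes[feat.start : feat.end], 3)
    for feat in reference.annotations:
        for s, e in feat.parts:
            classes[s:e] = np.minimum(classes[s:e], code[feat.kind])
    col_class = np.empty(len(aln), dtype=np.int8)
    last = 4
    for c, r in enumerate(aln.ref_coords):
        if r >= 0:
            last = classes[r]
        col_class[c] = last
    mat = aln.matrix()
    names = {0: "tRNA", 1: "rRNA", 2: "exon", 3: "intron", 4: "intergenic"}
    result: dict[str, tuple[float, float]] = {}
    k = mat.shape[0]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for cls_code, cls_name in names.items():
        mask = col_class == cls_code
        if not mask.any():
            continue
        idents = []
        for i, j in pairs:
            eq = mat[i, mask] == mat[j, mask]
            idents.append(100.0 * float(eq.mean()))
        arr = np.array(idents)
        result[cls_name] = (float(arr.mean()), float(arr.std()))
    return result
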