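"""Sequence/annotation data model and readers/writers for external formats.

All internal coordinates are 0-based, half-open, on the forward strand of the
stored orientation.  Conversions to the 1-based conventions of GenBank/VCF and
back happen only at the I/O boundary.  `N` bases are accepted in sequences but
are treated as missing data by every downstream diversity/variant computation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Plastome",
    "GeneFeature",
    "GroupMap",
    "PlastomeError",
    "read_sequences",
    "write_sequences",
    "read_annotations",
    "read_group_map",
    "write_group_map",
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "write_tsv",
    "read_tsv",
    "write_pi_bed",
    "read_pi_bed",
    "write_newick",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = ("CDS", "tRNA", "rRNA")


class PlastomeError(ValueError):
    """Raised for malformed sequence/annotation input."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene with one or more exonic parts in internal coordinates.

    Multiple parts encode introns (and the trans-spliced rps12); genes
    duplicated by the inverted repeat appear as two features sharing a name,
    each tagged ``IR-duplicated``.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str  # + | -
    parts: tuple[tuple[int, int], ...]
    copy_tag: str = "single"  # single | IR-duplicated

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise PlastomeError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.strand not in "+-":
            raise PlastomeError(f"bad strand {self.strand!r} for {self.name}")
        if not self.parts:
            raise PlastomeError(f"feature {self.name} has no parts")
        for s, e in self.parts:
            if not (0 <= s < e):
                raise PlastomeError(f"feature {self.name} has bad interval [{s},{e})")
        spans = sorted(self.parts)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise PlastomeError(f"feature {self.name} has overlapping parts")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.parts)

    def in_intron(self, pos: int) -> bool:
        return self.start <= pos < self.end and not self.contains(pos)


@dataclass
class Plastome:
    """One (usually circular) plastid genome with optional annotations."""

    id: str
    sequence: str
    species: str | None = None
    circular: bool = True
    annotations: list[GeneFeature] | None = None
    structure: "object | None" = None  # QuadripartiteStructure, set by structure module
    source_offset: int = 0  # rotation applied by canonicalize, for mapping back

    def __post_init__(self):
        if not self.sequence:
            raise PlastomeError(f"plastome {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise PlastomeError(
                f"plastome {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_annotations(self, annotations: list[GeneFeature]) -> "Plastome":
        for feat in annotations:
            if feat.end > len(self.sequence):
                raise PlastomeError(
                    f"feature {feat.name} [{feat.start},{feat.end}) exceeds "
                    f"sequence length {len(self.sequence)} of {self.id}"
                )
        return replace(self, annotations=list(annotations))


@dataclass
class GroupMap:
    """Sample id -> species group, with a stable group order."""

    mapping: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        if not self.group_order:
            self.group_order = seen
        else:
            missing = set(seen) - set(self.group_order)
            if missing:
                raise PlastomeError(f"groups missing from group order: {sorted(missing)}")

    def group_of(self, sample: str) -> str:
        try:
            return self.mapping[sample]
        except KeyError:
            raise PlastomeError(f"sample {sample!r} missing from group map") from None

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def validate_cover(self, sample_ids: Iterable[str]) -> None:
        for sid in sample_ids:
            self.group_of(sid)


# ---------------------------------------------------------------------------
# FASTA


def _normalize_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise PlastomeError(
            f"record {rec_id!r} contains non-ACGTN characters: {sorted(bad)}"
        )
    return seq


def read_sequences(path: str | os.PathLike) -> list[Plastome]:
    """Read a multi-record FASTA into Plastomes (uppercased, U->T)."""
    genomes: list[Plastome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise PlastomeError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        genomes.append(Plastome(id=rec.id, sequence=_normalize_sequence(str(rec.seq), rec.id)))
    if not genomes:
        raise PlastomeError(f"no FASTA records found in {path}")
    return genomes


def read_aligned_fasta(path: str | os.PathLike) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA (rows may contain '-') as (ids, rows)."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise PlastomeError(f"duplicate sequence id {rec.id!r} in {path}")
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace("U", "T"))
    if not ids:
        raise PlastomeError(f"no FASTA records found in {path}")
    return ids, rows


def write_aligned_fasta(ids: Sequence[str], rows: Sequence[str],
                        path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(ids, rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def write_sequences(genomes: Sequence[Plastome], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            desc = f" species={g.species}" if g.species else ""
            fh.write(f">{g.id}{desc}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations (GenBank / GFF3)

_GB_KIND = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _tag_ir_duplicates(features: list[GeneFeature]) -> list[GeneFeature]:
    from collections import Counter

    counts = Counter(f.name for f in features)
    return [
        replace(f, copy_tag="IR-duplicated") if counts[f.name] > 1 else f
        for f in features
    ]


def _read_genbank(path: str) -> Plastome:
    rec = SeqIO.read(path, "genbank")
    seq = _normalize_sequence(str(rec.seq), rec.id)
    features: list[GeneFeature] = []
    for feat in rec.features:
        kind = _GB_KIND.get(feat.type)
        if kind is None:
            continue
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        # Biopython locations are already 0-based half-open.
        parts = tuple(sorted((int(p.start), int(p.end)) for p in feat.location.parts))
        strand = "-" if feat.location.strand == -1 else "+"
        for s, e in parts:
            if e > len(seq):
                raise PlastomeError(
                    f"feature {name} [{s},{e}) exceeds sequence length {len(seq)}"
                )
        features.append(GeneFeature(name=name, kind=kind, strand=strand, parts=parts))
    return Plastome(id=rec.id, sequence=seq).with_annotations(_tag_ir_duplicates(features))


def _read_gff3(path: str, genome: Plastome) -> Plastome:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    grouped: dict[str, dict] = {}
    for ftype in ("CDS", "tRNA", "rRNA"):
        for feat in db.features_of_type(ftype):
            name = feat.attributes.get("gene", feat.attributes.get("Name", [feat.id]))[0]
            key = feat.attributes.get("Parent", [f"{name}:{feat.start}"])[0]
            entry = grouped.setdefault(
                key, {"name": name, "kind": ftype, "strand": feat.strand, "parts": []}
            )
            # GFF3 is 1-based inclusive -> internal 0-based half-open.
            entry["parts"].append((feat.start - 1, feat.end))
    features = []
    for entry in grouped.values():
        parts = tuple(sorted(entry["parts"]))
        if parts[-1][1] > len(genome.sequence):
            raise PlastomeError(
                f"feature {entry['name']} exceeds sequence length {len(genome.sequence)}"
            )
        features.append(
            GeneFeature(
                name=entry["name"],
                kind=entry["kind"],
                strand=entry["strand"] if entry["strand"] in "+-" else "+",
                parts=parts,
            )
        )
    features.sort(key=lambda f: f.start)
    return genome.with_annotations(_tag_ir_duplicates(features))


def read_annotations(path: str | os.PathLike, genome: Plastome | None = None) -> Plastome:
    """Read gene annotations from GenBank (self-contained) or GFF3 (+ genome).

    Returns a Plastome carrying GeneFeatures in internal coordinates.  Joined
    (multi-exon / trans-spliced) locations become multi-part features.
    """
    path = str(path)
    with open(path) as fh:
        head = fh.read(64)
    if head.startswith("LOCUS"):
        gb = _read_genbank(path)
        if genome is not None:
            if gb.sequence != genome.sequence:
                raise PlastomeError(
                    f"GenBank sequence for {gb.id} does not match genome {genome.id}"
                )
            return genome.with_annotations(gb.annotations)
        return gb
    if genome is None:
        raise PlastomeError("GFF3 annotation requires the genome sequence")
    return _read_gff3(path, genome)


def write_gff3(genome: Plastome, path: str | os.PathLike) -> None:
    """Write annotations as GFF3 (1-based inclusive), one gene per Parent."""
    if genome.annotations is None:
        raise PlastomeError(f"genome {genome.id} has no annotations to write")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for i, feat in enumerate(genome.annotations):
            gid = f"gene{i:04d}"
            fh.write(
                "\t".join(
                    [
                        genome.id, "plastmarker", "gene",
                        str(feat.start + 1), str(feat.end), ".", feat.strand, ".",
                        f"ID={gid};Name={feat.name};gene={feat.name};copy_tag={feat.copy_tag}",
                    ]
                )
                + "\n"
            )
            for s, e in feat.parts:
                fh.write(
                    "\t".join(
                        [
                            genome.id, "plastmarker", feat.kind,
                            str(s + 1), str(e), ".", feat.strand, ".",
                            f"Parent={gid};gene={feat.name}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Group map TSV


def read_group_map(path: str | os.PathLike) -> GroupMap:
    mapping: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PlastomeError(f"group map line lacks two columns: {line!r}")
            sample, group = fields[0], fields[1]
            if sample in mapping:
                raise PlastomeError(f"sample {sample!r} listed twice in group map")
            mapping[sample] = group
            if group not in order:
                order.append(group)
    if not mapping:
        raise PlastomeError(f"empty group map {path}")
    return GroupMap(mapping=mapping, group_order=order)


def write_group_map(groups: GroupMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.mapping.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# VCF (4.2, 1-based, left-aligned InDels)

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=KIND,Number=1,Type=String,Description="SNP or InDel">',
    '##INFO=<ID=REGION,Number=1,Type=String,Description="CDS/intron/intergenic/tRNA/rRNA">',
    '##INFO=<ID=LOCUS,Number=1,Type=String,Description="gene or flanking-gene pair">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="haploid allele index">',
]


def write_vcf(variants: Sequence, reference: Plastome, sample_ids: Sequence[str],
              path: str | os.PathLike) -> None:
    """Write VariantRecords as haploid VCF 4.2 (internal 0-based -> POS 1-based)."""
    with open(path, "w") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        fh.write(f"##contig=<ID={reference.id},length={len(reference.sequence)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for v in sorted(variants, key=lambda v: v.ref_pos):
            alleles = [v.ref_allele] + list(v.alt_alleles)
            info = f"KIND={v.kind}"
            if getattr(v, "region", None):
                info += f";REGION={v.region}"
            if getattr(v, "locus_label", None):
                info += f";LOCUS={v.locus_label}"
            gts = []
            for sid in sample_ids:
                allele = v.calls.get(sid)
                gts.append("." if allele is None else str(alleles.index(allele)))
            fh.write(
                "\t".join(
                    [
                        reference.id, str(v.ref_pos + 1), ".", v.ref_allele,
                        ",".join(v.alt_alleles), ".", "PASS", info, "GT",
                    ]
                    + gts
                )
                + "\n"
            )


def read_vcf(path: str | os.PathLike):
    """Read a VCF written by :func:`write_vcf` back into VariantRecords."""
    from .comparative import VariantRecord

    records = []
    sample_ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            f = line.split("\t")
            ref, alts = f[3], f[4].split(",")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            alleles = [ref] + alts
            calls = {
                sid: (None if gt == "." else alleles[int(gt)])
                for sid, gt in zip(sample_ids, f[9:])
            }
            calls = {s: a for s, a in calls.items() if a is not None}
            records.append(
                VariantRecord(
                    kind=info.get("KIND", "SNP"),
                    ref_pos=int(f[1]) - 1,
                    ref_allele=ref,
                    alt_alleles=tuple(alts),
                    calls=calls,
                    region=info.get("REGION"),
                    locus_label=info.get("LOCUS"),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Generic TSV tables (pandas-backed), Pi BED, newick


def write_tsv(df, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def write_pi_bed(profile, chrom: str, path: str | os.PathLike) -> None:
    """Window Pi as BED (0-based half-open) with the Pi value in the score column."""
    with open(path, "w") as fh:
        for start, end, pi in zip(profile.window_starts, profile.window_ends, profile.pi):
            fh.write(f"{chrom}\t{start}\t{end}\t{chrom}:{start}-{end}\t{pi:.6g}\n")


def read_pi_bed(path: str | os.PathLike) -> list[tuple[int, int, float]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append((int(f[1]), int(f[2]), float(f[4])))
    return rows


def write_newick(newick: str, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")
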