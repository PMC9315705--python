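"""Perfect microsatellite (SSR) scanning in the style of the MISA tool.

Detects all maximal perfect tandem runs of primitive 1-6 bp motifs meeting
per-motif-length minimum copy numbers (defaults 1:10, 2:5, 3:5, 4:4, 5:3,
6:3, i.e. a mononucleotide run qualifies at >=10 bp).  Runs are reported on
forward-strand coordinates; only simple (uninterrupted) repeats are found --
no compound or imperfect SSR merging.  Runs containing N are excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import Plastome, revcomp
from .structure import QuadripartiteStructure

__all__ = ["SSRConfig", "SSRRecord", "scan_ssrs", "summarize_ssrs", "canonical_motif"]

MOTIF_CLASS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRConfig:
    """Minimum copy number per motif length (MISA-style thresholds)."""

    min_repeats: tuple[tuple[int, int], ...] = ((1, 10), (2, 5), (3, 5), (4, 4), (5, 3), (6, 3))

    def __post_init__(self):
        for m, r in self.min_repeats:
            if not 1 <= m <= 6:
                raise ValueError(f"motif length {m} outside 1-6")
            if r < 2:
                raise ValueError(f"minimum copy number {r} for motif length {m} < 2")

    def threshold(self, motif_len: int) -> int | None:
        return dict(self.min_repeats).get(motif_len)

    @classmethod
    def parse(cls, text: str) -> "SSRConfig":
        """Parse '1=10,2=5,...' CLI syntax."""
        pairs = []
        for item in text.split(","):
            m, r = item.split("=")
            pairs.append((int(m), int(r)))
        return cls(min_repeats=tuple(pairs))


@dataclass(frozen=True)
class SSRRecord:
    motif: str
    canonical_motif: str
    copies: int
    start: int
    end: int
    region: str | None = None

    def __post_init__(self):
        assert self.end - self.start == len(self.motif) * self.copies

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def motif_class(self) -> str:
        return MOTIF_CLASS[len(self.motif)]


def is_primitive(motif: str) -> bool:
    """True unless the motif is a whole power of a shorter word."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over all rotations of the motif and its revcomp."""
    rc = revcomp(motif)
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def scan_ssrs(genome: Plastome | str, config: SSRConfig | None = None) -> list[SSRRecord]:
    """All maximal perfect tandem runs meeting the thresholds.

    A run of period m is reported from the leftmost start of its maximal
    m-periodic tract, truncated to whole copies; its motif is primitive, so
    (A)12 is one record, never (AA)6.
    """
    seq = genome.sequence if isinstance(genome, Plastome) else genome
    config = config or SSRConfig()
    n = len(seq)
    records: list[SSRRecord] = []
    for m, min_copies in config.min_repeats:
        i = 0
        while i + m <= n:
            # find the maximal m-periodic tract starting at i (left-maximal by
            # construction: the scan only reaches i just past a period break)
            j = i
            while j + m < n and seq[j] == seq[j + m]:
                j += 1
            tract_len = (j - i) + m if j > i else 0
            if j == i:
                i += 1
                continue
            copies = tract_len // m
            motif = seq[i : i + m]
            if (
                copies >= min_copies
                and is_primitive(motif)
                and "N" not in seq[i : i + copies * m]
            ):
                records.append(
                    SSRRecord(
                        motif=motif,
                        canonical_motif=canonical_motif(motif),
                        copies=copies,
                        start=i,
                        end=i + copies * m,
                    )
                )
            # next tract cannot overlap this maximal one at the same period
            i = j + 1
    records.sort(key=lambda r: (r.start, len(r.motif)))
    return records


def assign_regions(records: list[SSRRecord], structure: QuadripartiteStructure) -> list[SSRRecord]:
    """Attach the LSC/IRb/SSC/IRa region of each record's start position."""
    from dataclasses import replace

    return [replace(r, region=structure.region_of(r.start)) for r in records]


def summarize_ssrs(
    records: list[SSRRecord], structure: QuadripartiteStructure | None = None
) -> dict:
    """Counts by motif-length class and (when structure is given) by region."""
    if structure is not None:
        records = assign_regions(records, structure)
    by_class = Counter(r.motif_class for r in records)
    summary = {
        "total": len(records),
        "by_class": {cls: by_class.get(cls, 0) for cls in MOTIF_CLASS.values()},
    }
    if structure is not None:
        by_region = Counter(r.region for r in records)
        summary["by_region"] = {reg: by_region.get(reg, 0) for reg in ("LSC", "IRb", "SSC", "IRa")}
    return summary
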