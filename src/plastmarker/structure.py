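"""Quadripartite LSC/IRb/SSC/IRa architecture detection for circular plastomes.

The detector finds the longest pair of *exact* inverted repeats on the circle
(seeded by 20-mer matches between the sequence and its reverse complement,
then extended maximally) and labels the longer single-copy segment LSC, the
shorter SSC.  Coordinates are reported in a canonical rotation with LSC
starting at 0 and segment order LSC-IRb-SSC-IRa; the rotation offset needed
to map back to the input is recorded on the structure.

Only exact IR pairs are supported: in the study system the two IR copies are
identical (concerted evolution), and the IRs are unique at ~22.8 kb, so an
ambiguous detection signals bad input and is raised as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import GeneFeature, Plastome, revcomp

__all__ = [
    "QuadripartiteStructure",
    "JunctionContext",
    "StructureNotFoundError",
    "AmbiguousStructureError",
    "detect_quadripartite",
    "canonicalize",
    "junction_report",
]

SEED_K = 20


class StructureNotFoundError(ValueError):
    """No inverted-repeat pair of at least min_ir_len was found."""


class AmbiguousStructureError(ValueError):
    """Multiple maximal IR candidate pairs of equal length."""


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The four intervals, in canonical (LSC-first) coordinates.

    Invariant: lsc_len + ssc_len + 2*ir_len == genome_length, and the IRa
    sequence is exactly the reverse complement of IRb.
    """

    genome_length: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    rotation_offset: int  # input position that becomes canonical position 0
    orientation_note: str = "SSC orientation as found"

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    def region_of(self, pos: int) -> str:
        """Region label (LSC/IRb/SSC/IRa) of a canonical coordinate."""
        for name, (s, e) in (
            ("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc), ("IRa", self.ira)
        ):
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside genome of length {self.genome_length}")

    def segment_lengths(self) -> dict[str, int]:
        return {"LSC": self.lsc_len, "IRb": self.ir_len, "SSC": self.ssc_len, "IRa": self.ir_len}


@dataclass(frozen=True)
class JunctionContext:
    """Nearest annotated gene per junction, with signed distance.

    Distance is >= 0 for a gene lying entirely on one side (bp from the
    junction to its nearest end, 0 when it abuts the junction) and negative
    for a gene spanning the junction, by the number of bp it extends across.
    """

    junctions: dict[str, tuple[str, int]]  # "LSC/IRb" -> (gene, signed bp)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.int64)
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[arr == ord("T")] = 3
    return out


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    return win[:n] @ powers


def _seed_matches(seq2: str, rc2: str, max_per_code: int = 64) -> list[tuple[int, int]]:
    """(i, j) pairs with seq2[i:i+k] == rc2[j:j+k]; over-frequent seeds masked."""
    a = _kmer_codes(_encode(seq2), SEED_K)
    b = _kmer_codes(_encode(rc2), SEED_K)
    order = np.argsort(b, kind="stable")
    b_sorted = b[order]
    left = np.searchsorted(b_sorted, a, side="left")
    right = np.searchsorted(b_sorted, a, side="right")
    pairs: list[tuple[int, int]] = []
    for i in range(a.size):
        lo, hi = left[i], right[i]
        if hi - lo == 0 or hi - lo > max_per_code:
            continue
        for idx in order[lo:hi]:
            pairs.append((i, int(idx)))
    return pairs


def _maximal_inverted_repeats(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """Maximal exact inverted-repeat pairs on the circle.

    Returns triples (start1, start2, length) in [0, n) with start1 < start2,
    copies disjoint on the circle.  Works on the doubled sequence so repeats
    spanning the origin are found.
    """
    n = len(seq)
    seq2 = seq + seq
    rc2 = revcomp(seq2)
    # Group seed matches by anti-diagonal: seq2[i:i+L] == rc2[j:j+L] stays on
    # constant i - j when extended, and maps to a forward/revcomp pair.
    by_diag: dict[int, list[int]] = {}
    for i, j in _seed_matches(seq2, rc2):
        by_diag.setdefault(i - j, []).append(i)
    found: set[tuple[int, int, int]] = set()
    n2 = 2 * n
    for diag, positions in by_diag.items():
        positions.sort()
        runs: list[tuple[int, int]] = []  # (start_i, end_i) of contiguous seeds
        run_start = positions[0]
        prev = positions[0]
        for p in positions[1:]:
            if p <= prev + SEED_K:  # overlapping/adjacent seeds -> same exact match
                prev = p
            else:
                runs.append((run_start, prev + SEED_K))
                run_start = prev = p
        runs.append((run_start, prev + SEED_K))
        for s, e in runs:
            # extend maximally by direct comparison
            while s > 0 and s - diag - 1 >= 0 and seq2[s - 1] == rc2[s - diag - 1]:
                s -= 1
            while e < n2 and e - diag < n2 and seq2[e] == rc2[e - diag]:
                e += 1
            length = e - s
            if length < min_len:
                continue
            length = min(length, n)  # cannot exceed one full monomer
            e = s + length
            # map revcomp window back to forward coordinates of seq2
            j = s - diag
            other_start = n2 - (j + length)
            a, b = s % n, other_start % n
            if a > b:
                a, b = b, a
            # the two copies must be disjoint on the circle
            if a == b:
                continue
            gap_ab = b - a
            gap_ba = n - gap_ab
            if length > gap_ab or length > gap_ba:
                continue
            found.add((a, b, length))
    return found


def detect_quadripartite(genome: Plastome, min_ir_len: int = 1000) -> QuadripartiteStructure:
    """Detect LSC/IRb/SSC/IRa on a circular plastome.

    Finds the longest exact inverted-repeat pair >= ``min_ir_len`` on the
    circle; the longer single-copy gap becomes LSC, the shorter SSC.  Raises
    :class:`StructureNotFoundError` when no qualifying pair exists and
    :class:`AmbiguousStructureError` when distinct maximal pairs tie.
    """
    n = len(genome.sequence)
    if n <= 4 * min_ir_len:
        raise StructureNotFoundError(
            f"genome {genome.id} ({n} bp) shorter than 4*min_ir_len={4*min_ir_len}"
        )
    candidates = _maximal_inverted_repeats(genome.sequence, min_ir_len)
    if not candidates:
        raise StructureNotFoundError(
            f"no inverted repeat >= {min_ir_len} bp in genome {genome.id}"
        )
    best_len = max(c[2] for c in candidates)
    best = sorted(c for c in candidates if c[2] == best_len)
    if len(best) > 1:
        raise AmbiguousStructureError(
            f"multiple maximal inverted-repeat pairs of {best_len} bp in "
            f"{genome.id}: {best}"
        )
    a, b, ir_len = best[0]
    gap1 = (a + ir_len, b)            # between copy1 end and copy2 start
    gap2 = (b + ir_len, a + n)        # wraps the origin
    len1 = gap1[1] - gap1[0]
    len2 = gap2[1] - gap2[0]
    if len1 == len2:
        raise AmbiguousStructureError(
            f"single-copy segments of equal length ({len1} bp) in {genome.id}; "
            "cannot label LSC/SSC"
        )
    if len1 > len2:
        lsc_start, lsc_len, ssc_len = gap1[0], len1, len2
        irb_start = b
    else:
        lsc_start, lsc_len, ssc_len = gap2[0] % n, len2, len1
        irb_start = a
    seq = genome.sequence
    seq2 = seq + seq
    irb_seq = seq2[irb_start : irb_start + ir_len]
    offset = lsc_start % n
    lsc = (0, lsc_len)
    irb = (lsc_len, lsc_len + ir_len)
    ssc = (lsc_len + ir_len, lsc_len + ir_len + ssc_len)
    ira = (lsc_len + ir_len + ssc_len, n)
    canon = seq2[offset : offset + n]
    assert canon[irb[0] : irb[1]] == irb_seq
    if canon[ira[0] : ira[1]] != revcomp(irb_seq):
        raise StructureNotFoundError(
            f"IR copies of {genome.id} are not exact reverse complements"
        )
    return QuadripartiteStructure(
        genome_length=n, lsc=lsc, irb=irb, ssc=ssc, ira=ira, rotation_offset=offset
    )


def canonicalize(genome: Plastome, structure: QuadripartiteStructure | None = None,
                 min_ir_len: int = 1000) -> Plastome:
    """Rotated copy of the genome with LSC first (order LSC-IRb-SSC-IRa).

    The rotation offset is recorded in ``source_offset`` so coordinates can be
    mapped back (input_pos = (canonical_pos + source_offset) mod n).  The
    strand is kept as given; only a rotation is applied.
    """
    if structure is None:
        structure = detect_quadripartite(genome, min_ir_len=min_ir_len)
    n = len(genome.sequence)
    off = structure.rotation_offset % n
    seq = genome.sequence[off:] + genome.sequence[:off]
    annotations = None
    if genome.annotations is not None:
        annotations = []
        for feat in genome.annotations:
            parts = []
            for s, e in feat.parts:
                s2, e2 = (s - off) % n, (e - off) % n
                if e2 == 0:
                    e2 = n
                if s2 < e2:
                    parts.append((s2, e2))
                else:  # part now wraps the origin; split it
                    parts.append((s2, n))
                    parts.append((0, e2))
            annotations.append(replace(feat, parts=tuple(sorted(parts))))
        annotations.sort(key=lambda f: f.start)
    canonical_structure = replace(structure, rotation_offset=0)
    return replace(
        genome,
        sequence=seq,
        annotations=annotations,
        structure=canonical_structure,
        source_offset=off,
    )


def junction_report(genome: Plastome, structure: QuadripartiteStructure) -> JunctionContext:
    """Nearest gene and signed distance at each of the four junctions.

    The genome must be in canonical coordinates (see :func:`canonicalize`)
    with annotations attached.
    """
    if not genome.annotations:
        raise ValueError(f"genome {genome.id} has no annotations for a junction report")
    n = structure.genome_length
    junctions = {
        "LSC/IRb": structure.irb[0],
        "IRb/SSC": structure.ssc[0],
        "SSC/IRa": structure.ira[0],
        "IRa/LSC": 0,  # circular origin
    }
    report: dict[str, tuple[str, int]] = {}
    for name, p in junctions.items():
        best: tuple[int, str] | None = None
        for feat in genome.annotations:
            a, b = feat.start, feat.end
            for pj in (p, p + n, p - n):  # circular distance
                if a < pj < b:
                    d = -min(pj - a, b - pj)
                elif a >= pj:
                    d = a - pj
                else:
                    d = pj - b
                if best is None or abs(d) < abs(best[0]) or (
                    abs(d) == abs(best[0]) and d < best[0]
                ):
                    best = (d, feat.name)
        assert best is not None
        report[name] = (best[1], best[0])
    return JunctionContext(junctions=report)
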