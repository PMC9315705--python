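"""Sliding-window and per-partition nucleotide diversity (Pi), DnaSP-style.

Pi is the average over all sequence pairs of per-site differences.  Windows
slide over *alignment* coordinates (default 500 bp window, 250 bp step);
within a window, columns containing a gap or N in any compared row are
removed before counting (complete deletion, DnaSP's default site handling).
A pairwise-deletion alternative is available behind a flag: there, each pair
is compared on the columns where both rows are ungapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .comparative import MultipleAlignment, classify_position
from .io_formats import GroupMap, Plastome
from .structure import QuadripartiteStructure

__all__ = ["DiversityConfig", "PiProfile", "sliding_pi", "summarize_pi"]

_GAP = ord("-")
_N = ord("N")


@dataclass(frozen=True)
class DiversityConfig:
    window: int = 500
    step: int = 250
    complete_deletion: bool = True
    hotspot_threshold: float = 0.01

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.step > self.window:
            raise ValueError("step must not exceed window")


@dataclass
class PiProfile:
    window_starts: np.ndarray
    window_ends: np.ndarray
    pi: np.ndarray  # NaN where a window has no comparable site
    midpoints: np.ndarray = field(init=False)

    def __post_init__(self):
        self.midpoints = (self.window_starts + self.window_ends) // 2

    def __len__(self) -> int:
        return len(self.pi)


def _pi_for_windows(mat: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                    complete_deletion: bool) -> np.ndarray:
    """Window Pi for a row matrix; vectorized over windows via cumulative sums."""
    k, L = mat.shape
    missing = (mat == _GAP) | (mat == _N)
    any_missing = missing.any(axis=0)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    npairs = len(pairs)
    diff = np.zeros((npairs, L), dtype=bool)
    ok = np.zeros((npairs, L), dtype=bool)
    for idx, (i, j) in enumerate(pairs):
        if complete_deletion:
            valid = ~any_missing
        else:
            valid = ~(missing[i] | missing[j])
        ok[idx] = valid
        diff[idx] = valid & (mat[i] != mat[j])
    cdiff = np.concatenate(
        [np.zeros((npairs, 1), dtype=np.int64), np.cumsum(diff, axis=1)], axis=1
    )
    cok = np.concatenate(
        [np.zeros((npairs, 1), dtype=np.int64), np.cumsum(ok, axis=1)], axis=1
    )
    out = np.empty(len(starts))
    for w, (s, e) in enumerate(zip(starts, ends)):
        d = cdiff[:, e] - cdiff[:, s]
        m = cok[:, e] - cok[:, s]
        with np.errstate(invalid="ignore", divide="ignore"):
            per_pair = np.where(m > 0, d / np.maximum(m, 1), np.nan)
        out[w] = np.nan if np.isnan(per_pair).all() else np.nanmean(per_pair)
    return out


def _window_grid(L: int, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    if window >= L:
        return np.array([0]), np.array([L])
    starts = np.arange(0, L - window + 1, step)
    if starts[-1] + window < L:  # trailing partial window covers the tail
        starts = np.append(starts, L - window)
    return starts, starts + window


def sliding_pi(aln: MultipleAlignment, config: DiversityConfig | None = None,
               sample_ids: list[str] | None = None) -> PiProfile:
    """Per-window nucleotide diversity over alignment coordinates."""
    config = config or DiversityConfig()
    ids = sample_ids or aln.ids
    if len(ids) < 2:
        raise ValueError("Pi needs at least 2 sequences")
    mat = np.vstack(
        [np.frombuffer(aln.row(sid).encode(), dtype=np.uint8) for sid in ids]
    )
    L = mat.shape[1]
    if config.window > L:
        warnings.warn(
            f"window {config.window} exceeds alignment length {L}; "
            "using a single whole-alignment window"
        )
    starts, ends = _window_grid(L, config.window, config.step)
    pi = _pi_for_windows(mat, starts, ends, config.complete_deletion)
    return PiProfile(window_starts=starts, window_ends=ends, pi=pi)


def overall_pi(aln: MultipleAlignment, sample_ids: list[str] | None = None,
               complete_deletion: bool = True) -> float:
    """Whole-alignment Pi for a sample subset (one window spanning everything)."""
    ids = sample_ids or aln.ids
    mat = np.vstack(
        [np.frombuffer(aln.row(sid).encode(), dtype=np.uint8) for sid in ids]
    )
    L = mat.shape[1]
    val = _pi_for_windows(mat, np.array([0]), np.array([L]), complete_deletion)[0]
    return float(val)


def summarize_pi(
    aln: MultipleAlignment,
    profile: PiProfile,
    structure: QuadripartiteStructure,
    groups: GroupMap | None = None,
    reference: Plastome | None = None,
    hotspot_threshold: float = 0.01,
) -> dict:
    """Region averages/ranges, per-group overall Pi, and hotspot windows.

    Windows are assigned to LSC/SSC/IR by the region of their midpoint's
    reference coordinate; hotspot windows (Pi > threshold) are labelled by
    the locus at their midpoint when annotations are supplied.
    """
    # map alignment columns to reference coordinates (nearest on the left)
    ref_at_col = np.maximum.accumulate(
        np.where(aln.ref_coords >= 0, aln.ref_coords, -1)
    )

    def col_region(col: int) -> str:
        r = max(int(ref_at_col[min(col, len(ref_at_col) - 1)]), 0)
        reg = structure.region_of(r)
        return "IR" if reg in ("IRa", "IRb") else reg

    # a window belongs to a region only when fully contained in it; windows
    # straddling a junction are excluded from the per-region averages
    regions = []
    for s, e in zip(profile.window_starts, profile.window_ends):
        r1, r2 = col_region(int(s)), col_region(int(e) - 1)
        regions.append(r1 if r1 == r2 else "junction")
    regions = np.array(regions)
    summary: dict = {"regions": {}}
    for reg in ("LSC", "SSC", "IR"):
        vals = profile.pi[(regions == reg) & ~np.isnan(profile.pi)]
        if vals.size:
            summary["regions"][reg] = {
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n_windows": int(vals.size),
            }
    if groups is not None:
        per_group = {}
        for g in groups.group_order:
            members = [s for s in groups.samples_in(g) if s in aln.ids]
            if len(members) >= 2:
                per_group[g] = overall_pi(aln, members)
        summary["per_group"] = per_group
    hotspots = []
    for w in np.flatnonzero(~np.isnan(profile.pi) & (profile.pi > hotspot_threshold)):
        entry = {
            "start": int(profile.window_starts[w]),
            "end": int(profile.window_ends[w]),
            "pi": float(profile.pi[w]),
        }
        if reference is not None and reference.annotations:
            r = int(max(ref_at_col[min(profile.midpoints[w], len(ref_at_col) - 1)], 0))
            entry["region"], entry["locus"] = classify_position(reference, r)
        hotspots.append(entry)
    summary["hotspots"] = hotspots
    return summary
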