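"""ChIP-seq integration: interval overlap partitions, promoter-bound gene
sets, peak-burden comparisons and anchor-centered signal matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel
from .peaks import Peak, PeakSet, _in_promoter

__all__ = [
    "CoverageTrack", "SignalMatrix", "OverlapResult",
    "overlap_peak_sets", "promoter_bound_genes", "compare_peak_burden",
    "signal_matrix",
]


@dataclass
class CoverageTrack:
    """Piecewise-constant coverage with bedGraph semantics.

    Positions without a record read as zero.  Per chromosome the intervals
    are kept sorted and non-overlapping with a prefix-integral for O(log n)
    window sums.
    """

    _chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict)

    @classmethod
    def from_bedgraph(cls, source: str | Iterable[str]) -> "CoverageTrack":
        if isinstance(source, str):
            source = source.splitlines()
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for lineno, line in enumerate(source, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise ValueError(f"line {lineno}: bedGraph needs 4 columns")
            start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            if value < 0:
                raise ValueError(f"line {lineno}: negative coverage")
            per_chrom.setdefault(cols[0], []).append((start, end, value))
        track = cls()
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            values = np.array([v for _, _, v in ivs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            track._chroms[chrom] = (starts, ends, values, cum)
        return track

    @property
    def chroms(self) -> set:
        return set(self._chroms)

    def _integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Cumulative coverage integral from -inf to each position x."""
        starts, ends, values, cum = self._chroms[chrom]
        x = np.asarray(x, dtype=np.int64)
        idx = np.searchsorted(starts, x, side="right") - 1
        out = np.zeros(len(x), dtype=float)
        valid = idx >= 0
        iv = idx[valid]
        inside = x[valid] < ends[iv]
        res = np.where(
            inside,
            cum[iv] + values[iv] * (x[valid] - starts[iv]),
            cum[iv + 1],
        )
        out[valid] = res
        return out

    def window_means(self, chrom: str, start: int, n_bins: int,
                     bin_width: int) -> np.ndarray:
        """Mean coverage in n_bins consecutive bins from ``start``."""
        if chrom not in self._chroms:
            return np.zeros(n_bins)
        edges = start + bin_width * np.arange(n_bins + 1)
        integrals = self._integral(chrom, edges)
        return np.diff(integrals) / bin_width

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values, _ = self._chroms[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0


@dataclass
class SignalMatrix:
    matrix: np.ndarray           # anchors x bins, minus-strand rows reversed
    mean_profile: np.ndarray     # column means
    bin_offsets: np.ndarray      # bin-center offsets relative to the anchor
    n_missing_chrom: int = 0


@dataclass
class OverlapResult:
    a_only: list[Peak]
    b_only: list[Peak]
    cobound_regions: list[tuple[str, int, int]]
    n_a_overlapping: int
    n_b_overlapping: int

    @property
    def n_cobound(self) -> int:
        return len(self.cobound_regions)


def _merge(regions: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(regions):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def overlap_peak_sets(setA: PeakSet, setB: PeakSet,
                      min_overlap: int = 1) -> OverlapResult:
    """Partition two peak sets into A-only, B-only and co-bound.

    A peak is co-bound iff it intersects >= min_overlap bp of any peak from
    the other set (counted once regardless of how many partners it has).
    Co-bound regions are the merged unions of all co-bound peaks.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom_b: dict[str, list[Peak]] = {}
    for p in setB.peaks:
        by_chrom_b.setdefault(p.chrom, []).append(p)
    for lst in by_chrom_b.values():
        lst.sort(key=lambda p: p.start)

    a_hit = [False] * len(setA.peaks)
    b_hit: dict[str, np.ndarray] = {
        c: np.zeros(len(lst), dtype=bool) for c, lst in by_chrom_b.items()}
    for i, pa in enumerate(setA.peaks):
        lst = by_chrom_b.get(pa.chrom, [])
        if not lst:
            continue
        starts = np.array([p.start for p in lst])
        ends = np.array([p.end for p in lst])
        ov = np.minimum(ends, pa.end) - np.maximum(starts, pa.start)
        hits = ov >= min_overlap
        if hits.any():
            a_hit[i] = True
            b_hit[pa.chrom] |= hits

    a_only = [p for p, h in zip(setA.peaks, a_hit) if not h]
    b_only = []
    cobound: list[tuple[str, int, int]] = []
    for chrom, lst in by_chrom_b.items():
        for p, h in zip(lst, b_hit[chrom]):
            if h:
                cobound.append((p.chrom, p.start, p.end))
            else:
                b_only.append(p)
    n_a_overlapping = sum(a_hit)
    n_b_overlapping = int(sum(m.sum() for m in b_hit.values()))
    for p, h in zip(setA.peaks, a_hit):
        if h:
            cobound.append((p.chrom, p.start, p.end))
    return OverlapResult(a_only, b_only, _merge(cobound),
                         n_a_overlapping, n_b_overlapping)


def promoter_bound_genes(
    peaks: PeakSet,
    genes: Mapping[str, TranscriptModel],
    window: tuple[int, int] = (1000, 1000),
) -> set[str]:
    """Genes whose strand-aware TSS window contains >= 1 peak anchor."""
    up, down = window
    anchors_by_chrom: dict[str, list[int]] = {}
    for p in peaks.peaks:
        anchors_by_chrom.setdefault(p.chrom, []).append(p.anchor)
    bound = set()
    for gid, m in genes.items():
        for a in anchors_by_chrom.get(m.chrom, ()):
            if _in_promoter(m, a, up, down):
                bound.add(gid)
                break
    return bound


def compare_peak_burden(
    groupA: set, groupB: set, counts: Mapping[str, int],
) -> tuple[float, float, float]:
    """Medians of per-gene peak counts in two disjoint gene groups plus a
    two-sided Mann-Whitney p-value (normal approximation, tie-corrected)."""
    if groupA & groupB:
        raise ValueError("groups must be disjoint")
    xs = [counts[g] for g in groupA if g in counts]
    ys = [counts[g] for g in groupB if g in counts]
    if not xs or not ys:
        raise ValueError("each group needs >= 1 gene with a peak count")
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(np.median(xs)), float(np.median(ys)), float(res.pvalue)


def signal_matrix(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int = 4000,
    bin_width: int = 50,
) -> SignalMatrix:
    """Anchor-centered binned coverage matrix spanning [-flank, +flank).

    Minus-strand rows are reversed so the left edge is always upstream in
    transcript orientation.  Anchors on chromosomes absent from the track
    contribute zero-filled rows (counted in ``n_missing_chrom``).
    """
    if flank <= 0 or bin_width <= 0 or flank % bin_width:
        raise ValueError("flank must be a positive multiple of bin_width")
    n_bins = 2 * flank // bin_width
    rows = np.zeros((len(anchors), n_bins))
    missing = 0
    for i, (chrom, pos, strand) in enumerate(anchors):
        if chrom not in track.chroms:
            missing += 1
            continue
        row = track.window_means(chrom, pos - flank, n_bins, bin_width)
        if strand == "-":
            row = row[::-1]
        rows[i] = row
    offsets = -flank + bin_width * (np.arange(n_bins) + 0.5)
    profile = rows.mean(axis=0) if len(anchors) else np.zeros(n_bins)
    return SignalMatrix(rows, profile, offsets, missing)
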