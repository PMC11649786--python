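"""Peak I/O, genomic-feature annotation, gene burdens, permutation testing
and gene-set intersection.

Peaks are anchored at their summit (midpoint when absent) and classified
against representative transcripts with the precedence
promoter > utr5 > utr3 > cds_exon > intron > tts > intergenic; the gene is
the matching transcript whose TSS is nearest to the anchor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

__all__ = [
    "Peak", "PeakSet", "PeakAnnotation", "read_peaks",
    "annotate_peaks", "peaks_per_gene", "m6a_positive_genes",
    "permutation_test_counts", "filter_deg", "intersect_gene_sets",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = (
    "promoter", "utr5", "utr3", "cds_exon", "intron", "tts", "intergenic")

#: nearest-TSS assignment radius for intergenic peaks (bp)
INTERGENIC_RADIUS = 100_000


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit_offset: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"peak end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.summit_offset is not None and not (
                0 <= self.summit_offset < self.end - self.start):
            raise ValueError("summit_offset outside peak interval")

    @property
    def anchor(self) -> int:
        """Summit position, or the interval midpoint when absent."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    label: str
    peaks: list[Peak] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.label:
            raise ValueError("PeakSet label must be non-empty")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class PeakCall:
    """Classification of one peak."""
    feature_class: str
    gene_id: str | None
    distance_to_tss: int | None


class PeakAnnotation(dict):
    """Mapping peak index -> PeakCall, plus the annotated PeakSet."""

    def __init__(self, peakset: PeakSet, calls: Mapping[int, PeakCall]):
        super().__init__(calls)
        self.peakset = peakset

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, call in sorted(self.items()):
            p = self.peakset.peaks[i]
            rows.append((p.chrom, p.start, p.end, p.anchor, call.feature_class,
                         call.gene_id, call.distance_to_tss))
        return pd.DataFrame(rows, columns=[
            "chrom", "start", "end", "anchor", "feature_class",
            "gene_id", "distance_to_tss"])


def read_peaks(source: str | Iterable[str], dialect: str = "bed",
               label: str = "peaks") -> PeakSet:
    """Read BED3+ or ENCODE narrowPeak records into a PeakSet.

    Records with end <= start are collected in ``PeakSet.rejected`` with
    their line number; non-integer coordinates raise a ValueError.
    narrowPeak column 10 becomes the summit offset (-1 means absent).
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if isinstance(source, str):
        source = source.splitlines()
    peaks: list[Peak] = []
    rejected: list[tuple[int, str]] = []
    min_cols = 3 if dialect == "bed" else 10
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < min_cols:
            raise ValueError(
                f"line {lineno}: expected >= {min_cols} columns, got {len(cols)}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinate") from exc
        if end <= start:
            rejected.append((lineno, f"end <= start ({start}, {end})"))
            continue
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        score = None
        if len(cols) > 4 and cols[4] != ".":
            try:
                score = float(cols[4])
            except ValueError:
                score = None
        summit = None
        if dialect == "narrowPeak":
            summit_col = int(cols[9])
            if summit_col >= 0:
                summit = summit_col
        peaks.append(Peak(cols[0], start, end, summit_offset=summit,
                          score=score, name=name))
    return PeakSet(label=label, peaks=peaks, rejected=rejected)


def _in_promoter(model: TranscriptModel, pos: int, up: int, down: int) -> bool:
    d = model.tss_signed_distance(pos)
    return -up <= d <= down


def _in_tts(model: TranscriptModel, pos: int, up: int, down: int) -> bool:
    d = pos - model.tes
    if model.strand == "-":
        d = -d
    return -up <= d <= down


def _contains(ivs: Sequence[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in ivs)


def classify_anchor(
    chrom: str,
    pos: int,
    genes: Mapping[str, TranscriptModel],
    promoter_window: tuple[int, int] = (1000, 1000),
    tts_window: tuple[int, int] = (1000, 1000),
    radius: int = INTERGENIC_RADIUS,
) -> PeakCall:
    """Classify a single anchor point (used per peak by annotate_peaks)."""
    up, down = promoter_window
    matches: dict[str, list[TranscriptModel]] = {c: [] for c in FEATURE_CLASSES}
    for m in genes.values():
        if m.chrom != chrom:
            continue
        if _in_promoter(m, pos, up, down):
            matches["promoter"].append(m)
        if _contains(m.utr5, pos):
            matches["utr5"].append(m)
        if _contains(m.utr3, pos):
            matches["utr3"].append(m)
        if _contains(m.cds, pos):
            matches["cds_exon"].append(m)
        s0, s1 = m.span
        if s0 <= pos < s1 and not _contains(m.exons, pos):
            matches["intron"].append(m)
        if _in_tts(m, pos, *tts_window):
            matches["tts"].append(m)

    for cls in ("promoter", "utr5", "utr3", "cds_exon", "intron", "tts"):
        if matches[cls]:
            best = min(matches[cls],
                       key=lambda m: (abs(pos - m.tss), m.transcript_id))
            return PeakCall(cls, best.gene_id, best.tss_signed_distance(pos))

    near = [m for m in genes.values()
            if m.chrom == chrom and abs(pos - m.tss) <= radius]
    if near:
        best = min(near, key=lambda m: (abs(pos - m.tss), m.transcript_id))
        return PeakCall("intergenic", best.gene_id, best.tss_signed_distance(pos))
    return PeakCall("intergenic", None, None)


def annotate_peaks(
    peaks: PeakSet,
    genes: Mapping[str, TranscriptModel],
    promoter_window: tuple[int, int] = (1000, 1000),
    tts_window: tuple[int, int] = (1000, 1000),
    radius: int = INTERGENIC_RADIUS,
) -> PeakAnnotation:
    """Annotate every peak to a feature class and nearest-TSS gene."""
    if not genes:
        raise ValueError("empty annotation")
    calls = {
        i: classify_anchor(p.chrom, p.anchor, genes, promoter_window,
                           tts_window, radius)
        for i, p in enumerate(peaks.peaks)
    }
    return PeakAnnotation(peaks, calls)


def peaks_per_gene(annotation: PeakAnnotation) -> dict[str, int]:
    """Count non-intergenic peaks per assigned gene."""
    counts: dict[str, int] = {}
    for call in annotation.values():
        if call.feature_class == "intergenic" or call.gene_id is None:
            continue
        counts[call.gene_id] = counts.get(call.gene_id, 0) + 1
    return counts


def m6a_positive_genes(counts: Mapping[str, int]) -> set[str]:
    """Genes carrying at least one peak."""
    return {g for g, n in counts.items() if n >= 1}


def permutation_test_counts(
    setA: PeakSet | int,
    setB: PeakSet | int,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[int, float]:
    """Permutation test for a difference in total peak counts.

    The observed statistic is |nA - nB|.  Under the null each of the
    nA + nB pooled peaks is reassigned to a condition with probability 1/2;
    p = (1 + #{perm stat >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    nA = setA if isinstance(setA, int) else len(setA)
    nB = setB if isinstance(setB, int) else len(setB)
    if nA == 0 and nB == 0:
        raise ValueError("both peak sets are empty")
    total = nA + nB
    observed = abs(nA - nB)
    rng = np.random.default_rng(seed)
    perm_a = rng.binomial(total, 0.5, size=n_perm)
    perm_stat = np.abs(2 * perm_a - total)
    p = (1 + int(np.sum(perm_stat >= observed))) / (n_perm + 1)
    return observed, p


def filter_deg(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.01,
) -> set[str]:
    """DEGs: |log2fc| strictly greater than the fold-change threshold AND
    padj strictly below the significance threshold."""
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    for col in ("gene_id", "log2fc", "padj"):
        if col not in table.columns:
            raise ValueError(f"DE table missing column: {col}")
    mask = (table["log2fc"].abs() > lfc_threshold) & (table["padj"] < padj_threshold)
    return set(table.loc[mask, "gene_id"].astype(str))


def intersect_gene_sets(
    sets: Mapping[str, set],
) -> dict[frozenset, int]:
    """Cardinality of every exclusive membership region of >= 2 named sets.

    Returns a mapping frozenset-of-labels -> number of elements belonging to
    exactly those sets (2^n - 1 regions; empty regions reported as 0).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    labels = list(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions[frozenset(combo)] = 0
    universe = set().union(*sets.values())
    for el in universe:
        member = frozenset(lbl for lbl in labels if el in sets[lbl])
        regions[member] += 1
    return regions
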