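"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately recompute results by enumeration (per-base walks,
all-pairs interval scans, per-element set bookkeeping) rather than calling
the library's algorithms.
"""

from __future__ import annotations

import math

import numpy as np

from epimeta.peaks import PeakCall


def brute_project_bin(pos, model, mg):
    """Metagene bin of a genomic position by explicit base-by-base walk."""
    bases = [p for s, e in model.exons for p in range(s, e)]
    if model.strand == "-":
        bases = bases[::-1]
    l5, lc, l3 = model.region_lengths()
    b1, b2, b3, b4, _ = mg.region_boundaries
    if pos in bases:
        t = bases.index(pos)
        if t < l5:
            return b1 + math.floor(mg.bins_utr5 * t / l5)
        if t < l5 + lc:
            return b2 + math.floor(mg.bins_cds * (t - l5) / lc)
        if t < l5 + lc + l3:
            return b3 + math.floor(mg.bins_utr3 * (t - l5 - lc) / l3)
        return None
    s0, s1 = model.span
    if s0 <= pos < s1:
        return None  # intron
    if mg.flank_bp == 0:
        return None
    if model.strand == "+":
        up = list(range(model.tss - mg.flank_bp, model.tss))
        down = list(range(s1, s1 + mg.flank_bp))
    else:
        up = list(range(model.tss + mg.flank_bp, model.tss, -1))
        down = list(range(s0 - 1, s0 - 1 - mg.flank_bp, -1))
    if pos in up:
        i = up.index(pos)
        return math.floor(mg.bins_flank5 * i / mg.flank_bp)
    if pos in down:
        i = down.index(pos)
        return b4 + math.floor(mg.bins_flank3 * i / mg.flank_bp)
    return None


def brute_classify(chrom, pos, genes, promoter_window=(1000, 1000),
                   tts_window=(1000, 1000), radius=100_000):
    """Peak classification by plain per-transcript looping with the same
    precedence and nearest-TSS gene rule."""
    up, down = promoter_window
    tup, tdown = tts_window
    hits = {c: [] for c in ("promoter", "utr5", "utr3", "cds_exon",
                            "intron", "tts")}
    for m in genes.values():
        if m.chrom != chrom:
            continue
        d = (pos - m.tss) if m.strand == "+" else (m.tss - pos)
        if -up <= d <= down:
            hits["promoter"].append(m)
        for cls, ivs in (("utr5", m.utr5), ("utr3", m.utr3),
                         ("cds_exon", m.cds)):
            if any(s <= pos < e for s, e in ivs):
                hits[cls].append(m)
        s0, s1 = m.span
        in_exon = any(s <= pos < e for s, e in m.exons)
        if s0 <= pos < s1 and not in_exon:
            hits["intron"].append(m)
        dt = (pos - m.tes) if m.strand == "+" else (m.tes - pos)
        if -tup <= dt <= tdown:
            hits["tts"].append(m)
    for cls in ("promoter", "utr5", "utr3", "cds_exon", "intron", "tts"):
        if hits[cls]:
            best = min(hits[cls], key=lambda m: (abs(pos - m.tss),
                                                 m.transcript_id))
            d = (pos - best.tss) if best.strand == "+" else (best.tss - pos)
            return PeakCall(cls, best.gene_id, d)
    near = [m for m in genes.values()
            if m.chrom == chrom and abs(pos - m.tss) <= radius]
    if near:
        best = min(near, key=lambda m: (abs(pos - m.tss), m.transcript_id))
        d = (pos - best.tss) if best.strand == "+" else (best.tss - pos)
        return PeakCall("intergenic", best.gene_id, d)
    return PeakCall("intergenic", None, None)


def brute_overlap_flags(peaks_a, peaks_b, min_overlap=1):
    """All-pairs O(n^2) overlap flags for both peak lists."""
    a_hit = np.zeros(len(peaks_a), dtype=bool)
    b_hit = np.zeros(len(peaks_b), dtype=bool)
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            if pa.chrom != pb.chrom:
                continue
            ov = min(pa.end, pb.end) - max(pa.start, pb.start)
            if ov >= min_overlap:
                a_hit[i] = True
                b_hit[j] = True
    return a_hit, b_hit


def brute_venn(sets):
    """Exclusive region cardinalities by per-element membership lookup."""
    labels = list(sets)
    counts = {}
    for el in set().union(*sets.values()):
        key = frozenset(l for l in labels if el in sets[l])
        counts[key] = counts.get(key, 0) + 1
    return counts
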