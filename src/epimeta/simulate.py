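"""Seed-deterministic synthetic data with planted ground truth.

Every generator emits standards-compliant text (GTF, narrowPeak, bedGraph,
TSV) plus machine-readable truth, so each analysis stage can be tested
against known answers at toy scale.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .response import DoseResponseFit, DoseResponseMatrix

__all__ = [
    "GeneratorConfig", "SimulatedAnnotation", "SimulatedPeaks",
    "SimulatedChip", "DecayRecord",
    "make_genome_annotation", "make_peakset", "make_coverage_and_chip",
    "make_de_table", "make_decay_series", "make_dose_matrix",
]

REGIONS = ("flank5", "utr5", "cds", "utr3", "flank3")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_genes: int = 200
    chrom_sizes: dict = field(default_factory=lambda: {
        "chr1": 1_000_000, "chr2": 1_000_000})
    # peak placement weights over (flank5, utr5, cds, utr3, flank3)
    region_weights: tuple = (0.05, 0.10, 0.25, 0.55, 0.05)
    peak_counts: dict = field(default_factory=lambda: {
        "condA": 800, "condB": 600})
    peak_width: tuple = (100, 300)
    flank_bp: int = 1000
    # ChIP co-binding structure
    cobound_fraction: float = 0.3
    only_a_fraction: float = 0.2
    only_b_fraction: float = 0.2
    bump_sd: float = 150.0
    bump_amplitude: tuple = (20.0, 50.0)
    # DE table
    n_de_genes: int = 2000
    deg_fraction: float = 0.1
    deg_effect: float = 3.0
    # decay
    decay_ks: tuple = (0.2,)
    decay_sigma: float = 0.05
    decay_times: tuple = (0.0, 3.0, 6.0)
    # synergy
    synergy_delta: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.region_weights, dtype=float)
        if len(w) != 5 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("region_weights must be 5 non-negative values "
                             "with positive sum")
        for frac in (self.cobound_fraction, self.only_a_fraction,
                     self.only_b_fraction, self.deg_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator/condition."""
    return np.random.default_rng(
        [config.seed, zlib.crc32(stream.encode("utf-8"))])


# ---------------------------------------------------------------------------
# genome annotation


@dataclass
class SimulatedAnnotation:
    gtf: str
    truth: pd.DataFrame                      # one row per transcript
    transcripts: dict[str, TranscriptModel]  # planted longest, per gene
    all_models: list[TranscriptModel]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.transcripts)


def _transcript_to_genomic(exons, strand, t0, t1):
    """Genomic intervals of the spliced transcript slice [t0, t1)."""
    total = sum(e - s for s, e in exons)
    if strand == "-":
        t0, t1 = total - t1, total - t0
    out = []
    offset = 0
    for s, e in exons:
        length = e - s
        lo, hi = max(t0, offset), min(t1, offset + length)
        if lo < hi:
            out.append((s + lo - offset, s + hi - offset))
        offset += length
    return out


def _genomic_position(model: TranscriptModel, t: int) -> int:
    """Genomic position of spliced offset t (0 = 5' end of the transcript)."""
    total = model.exon_length
    plus_t = t if model.strand == "+" else total - 1 - t
    offset = 0
    for s, e in model.exons:
        if plus_t < offset + (e - s):
            return s + plus_t - offset
        offset += e - s
    raise IndexError(f"transcript offset {t} out of range")


def _gtf_line(chrom, feature, start, end, strand, gene, tx=None):
    attrs = f'gene_id "{gene}";'
    if tx is not None:
        attrs += f' transcript_id "{tx}";'
    return (f"{chrom}\tepimeta_sim\t{feature}\t{start + 1}\t{end}\t.\t"
            f"{strand}\t.\t{attrs}")


def make_genome_annotation(config: GeneratorConfig) -> SimulatedAnnotation:
    """Place non-overlapping genes with UTR/CDS structure on toy chromosomes."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(config, "annotation")
    chroms = list(config.chrom_sizes)
    lines: list[str] = []
    truth_rows = []
    transcripts: dict[str, TranscriptModel] = {}
    all_models: list[TranscriptModel] = []

    cursors = {c: 2000 for c in chroms}
    for gi in range(config.n_genes):
        gene = f"G{gi:04d}"
        chrom = chroms[gi % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        exon_lens = rng.integers(200, 600, size=n_exons)
        intron_lens = rng.integers(100, 1000, size=max(0, n_exons - 1))
        gap = int(rng.integers(2500, 5000))
        start = cursors[chrom] + gap
        span = int(exon_lens.sum() + intron_lens.sum())
        if start + span + 2000 > config.chrom_sizes[chrom]:
            raise ValueError(
                f"chromosome {chrom} too small to place gene {gene}")
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        cursors[chrom] = pos

        spliced = int(exon_lens.sum())
        u5 = max(30, int(spliced * rng.uniform(0.08, 0.18)))
        u3 = max(50, int(spliced * rng.uniform(0.20, 0.40)))
        # regions in transcript coordinates: [0,u5) utr5, [u5,spliced-u3) cds
        utr5_iv = _transcript_to_genomic(exons, strand, 0, u5)
        cds_iv = _transcript_to_genomic(exons, strand, u5, spliced - u3)
        utr3_iv = _transcript_to_genomic(exons, strand, spliced - u3, spliced)

        tid = f"{gene}.t1"
        model = TranscriptModel(gene, tid, chrom, strand, exons,
                                cds=cds_iv, utr5=utr5_iv, utr3=utr3_iv)
        transcripts[gene] = model
        all_models.append(model)
        lines.append(_gtf_line(chrom, "gene", exons[0][0], exons[-1][1],
                               strand, gene))
        lines.append(_gtf_line(chrom, "transcript", exons[0][0], exons[-1][1],
                               strand, gene, tid))
        for s, e in exons:
            lines.append(_gtf_line(chrom, "exon", s, e, strand, gene, tid))
        for feat, ivs in (("five_prime_utr", utr5_iv), ("CDS", cds_iv),
                          ("three_prime_utr", utr3_iv)):
            for s, e in ivs:
                lines.append(_gtf_line(chrom, feat, s, e, strand, gene, tid))
        truth_rows.append((gene, tid, chrom, strand, spliced, True))

        # optionally a strictly shorter second isoform (same structure,
        # 3'-truncated) so longest-isoform selection is exercised
        if rng.random() < 0.5 and spliced > 200:
            cut = int(rng.integers(spliced // 4, spliced // 2))
            short = spliced - cut
            tid2 = f"{gene}.t2"
            ex2 = _transcript_to_genomic(exons, strand, 0, short)
            u5b = min(u5, short)
            utr5b = _transcript_to_genomic(exons, strand, 0, u5b)
            cdsb = _transcript_to_genomic(exons, strand, u5b,
                                          max(u5b, min(short, spliced - u3)))
            utr3b = _transcript_to_genomic(
                exons, strand, max(u5b, min(short, spliced - u3)), short)
            model2 = TranscriptModel(gene, tid2, chrom, strand, ex2,
                                     cds=cdsb, utr5=utr5b, utr3=utr3b)
            all_models.append(model2)
            lines.append(_gtf_line(chrom, "transcript", ex2[0][0],
                                   ex2[-1][1], strand, gene, tid2))
            for s, e in ex2:
                lines.append(_gtf_line(chrom, "exon", s, e, strand, gene, tid2))
            for feat, ivs in (("five_prime_utr", utr5b), ("CDS", cdsb),
                              ("three_prime_utr", utr3b)):
                for s, e in ivs:
                    lines.append(_gtf_line(chrom, feat, s, e, strand, gene, tid2))
            truth_rows.append((gene, tid2, chrom, strand, short, False))

    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "transcript_id", "chrom", "strand", "spliced_length",
        "is_longest"])
    return SimulatedAnnotation("\n".join(lines) + "\n", truth, transcripts,
                               all_models)


# ---------------------------------------------------------------------------
# peak sets


@dataclass
class SimulatedPeaks:
    narrowpeak: str
    truth: pd.DataFrame   # peak name, gene_id, region, summit position


def make_peakset(config: GeneratorConfig, condition: str,
                 annotation: SimulatedAnnotation) -> SimulatedPeaks:
    """Draw peaks whose summits follow the configured region bias."""
    if condition not in config.peak_counts:
        raise ValueError(f"no peak count configured for {condition!r}")
    rng = _rng(config, f"peaks:{condition}")
    weights = np.asarray(config.region_weights, dtype=float)
    weights = weights / weights.sum()
    genes = annotation.gene_ids
    wlo, whi = config.peak_width
    lines = []
    truth_rows = []
    n = config.peak_counts[condition]
    for i in range(n):
        gene = genes[int(rng.integers(len(genes)))]
        model = annotation.transcripts[gene]
        region = REGIONS[int(rng.choice(5, p=weights))]
        l5, lc, l3 = model.region_lengths()
        # fall back to the cds when the drawn region is empty on this gene
        if region == "utr5" and l5 == 0:
            region = "cds"
        if region == "utr3" and l3 == 0:
            region = "cds"
        if region == "flank5":
            u = int(rng.integers(1, config.flank_bp + 1))
            pos = model.tss - u if model.strand == "+" else model.tss + u
        elif region == "flank3":
            d = int(rng.integers(0, config.flank_bp))
            if model.strand == "+":
                pos = model.span[1] + d
            else:
                pos = model.span[0] - 1 - d
        else:
            t0 = {"utr5": 0, "cds": l5, "utr3": l5 + lc}[region]
            tlen = {"utr5": l5, "cds": lc, "utr3": l3}[region]
            t = t0 + int(rng.integers(tlen))
            pos = _genomic_position(model, t)
        width = int(rng.integers(wlo, whi + 1))
        offset = int(rng.integers(10, width - 10))
        start = max(0, pos - offset)
        summit = pos - start
        name = f"{condition}_peak_{i}"
        score = int(rng.integers(100, 1000))
        lines.append("\t".join(map(str, [
            model.chrom, start, start + width, name, score, ".",
            round(rng.uniform(2, 20), 3), round(rng.uniform(5, 50), 3),
            round(rng.uniform(3, 30), 3), summit])))
        truth_rows.append((name, gene, region, pos))
    truth = pd.DataFrame(truth_rows,
                         columns=["name", "gene_id", "region", "summit_pos"])
    return SimulatedPeaks("\n".join(lines) + "\n", truth)


# ---------------------------------------------------------------------------
# ChIP coverage and co-binding


@dataclass
class SimulatedChip:
    bedgraph: dict[str, str]      # factor -> bedGraph text
    narrowpeak: dict[str, str]    # factor -> narrowPeak text
    bound: dict[str, set]         # factor -> planted bound gene set
    cobound: set                  # genes bound by both factors

    @property
    def anchors(self) -> dict[str, list[tuple[str, int, str]]]:
        return self._anchors

    def __post_init__(self):
        self._anchors = {}


def make_coverage_and_chip(config: GeneratorConfig,
                           annotation: SimulatedAnnotation) -> SimulatedChip:
    """Plant promoter-centred Gaussian coverage bumps for two factors with a
    configured co-binding fraction."""
    rng = _rng(config, "chip")
    genes = annotation.gene_ids
    status = []
    p_none = 1.0 - config.cobound_fraction - config.only_a_fraction \
        - config.only_b_fraction
    if p_none < -1e-9:
        raise ValueError("binding fractions sum above 1")
    draw = rng.choice(4, size=len(genes),
                      p=[config.cobound_fraction, config.only_a_fraction,
                         config.only_b_fraction, max(p_none, 0.0)])
    bound = {"factorA": set(), "factorB": set()}
    for gene, d in zip(genes, draw):
        if d == 0:
            bound["factorA"].add(gene)
            bound["factorB"].add(gene)
        elif d == 1:
            bound["factorA"].add(gene)
        elif d == 2:
            bound["factorB"].add(gene)
        status.append(d)

    bedgraph: dict[str, str] = {}
    narrowpeak: dict[str, str] = {}
    anchors: dict[str, list[tuple[str, int, str]]] = {}
    amp_lo, amp_hi = config.bump_amplitude
    for factor in ("factorA", "factorB"):
        rows: list[tuple[str, int, int, float]] = []
        peak_lines = []
        anchor_list = []
        for gene in sorted(bound[factor]):
            model = annotation.transcripts[gene]
            center = model.tss
            amp = rng.uniform(amp_lo, amp_hi)
            step = 10
            for x in range(center - 500, center + 500, step):
                mid = x + step / 2
                v = amp * math.exp(-((mid - center) ** 2)
                                   / (2 * config.bump_sd ** 2))
                if v >= 0.01 and x >= 0:
                    rows.append((model.chrom, x, x + step, round(v, 4)))
            start = max(0, center - 250)
            peak_lines.append("\t".join(map(str, [
                model.chrom, start, center + 250, f"{factor}_{gene}",
                int(amp * 10), ".", round(amp, 3), 10.0, 5.0,
                center - start])))
            anchor_list.append((model.chrom, center, model.strand))
        rows.sort()
        bedgraph[factor] = "\n".join(
            f"{c}\t{s}\t{e}\t{v}" for c, s, e, v in rows) + "\n"
        narrowpeak[factor] = "\n".join(peak_lines) + "\n"
        anchors[factor] = anchor_list

    sim = SimulatedChip(bedgraph, narrowpeak, bound,
                        bound["factorA"] & bound["factorB"])
    sim._anchors = anchors
    return sim


# ---------------------------------------------------------------------------
# DE tables, decay series, dose matrices


def make_de_table(config: GeneratorConfig) -> tuple[pd.DataFrame, set]:
    """DE table with planted DEGs: null log2fc ~ N(0, 0.25), DEGs shifted by
    +/- effect; planted DEGs get padj < 1e-4, null genes padj >= 0.02."""
    rng = _rng(config, "de")
    n = config.n_de_genes
    ids = [f"G{i:04d}" for i in range(n)]
    n_deg = int(round(n * config.deg_fraction))
    deg_idx = rng.choice(n, size=n_deg, replace=False)
    is_deg = np.zeros(n, dtype=bool)
    is_deg[deg_idx] = True
    lfc = rng.normal(0.0, 0.25, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc[is_deg] += signs[is_deg] * config.deg_effect
    padj = rng.uniform(0.02, 1.0, size=n)
    padj[is_deg] = rng.uniform(1e-8, 1e-4, size=n_deg)
    table = pd.DataFrame({"gene_id": ids, "log2fc": lfc, "padj": padj})
    return table, {ids[i] for i in deg_idx}


@dataclass
class DecayRecord:
    label: str
    times: np.ndarray
    abundances: np.ndarray
    true_k: float


def make_decay_series(config: GeneratorConfig,
                      n_series: int | None = None) -> list[DecayRecord]:
    """Exponential decay time courses, normalized to 100% at t=0, with
    multiplicative lognormal noise on the later time points."""
    rng = _rng(config, "decay")
    records = []
    ks = list(config.decay_ks)
    n_series = n_series if n_series is not None else len(ks)
    times = np.asarray(config.decay_times, dtype=float)
    if times[0] != 0:
        raise ValueError("decay time grid must start at 0")
    for i in range(n_series):
        k = ks[i % len(ks)]
        clean = 100.0 * np.exp(-k * times)
        noise = np.exp(rng.normal(0.0, config.decay_sigma, size=len(times)))
        noise[0] = 1.0  # t=0 defines the 100% normalization point
        records.append(DecayRecord(f"series_{i}", times, clean * noise, k))
    return records


def _loewe_expected(da: float, db: float, fit_a: DoseResponseFit,
                    fit_b: DoseResponseFit) -> float:
    """Analytic-inverse isobole solve used by the generator (independent of
    the scoring module's bisection)."""
    from scipy.optimize import brentq

    if da == 0 and db == 0:
        return 0.0
    if db == 0:
        return float(fit_a(da))
    if da == 0:
        return float(fit_b(db))

    def f(y):
        return da / fit_a.inverse(y) + db / fit_b.inverse(y) - 1.0

    lo = max(fit_a.floor, fit_b.floor) + 1e-9
    hi = min(fit_a.ceiling, fit_b.ceiling) - 1e-9
    return float(brentq(f, lo, hi, xtol=1e-10))


def make_dose_matrix(
    config: GeneratorConfig,
) -> tuple[DoseResponseMatrix, float, DoseResponseFit, DoseResponseFit]:
    """Dose-response matrix built from two random 4PL monotherapies under
    Loewe additivity plus a planted excess of ``synergy_delta`` percentage
    points on every combination cell."""
    rng = _rng(config, "synergy")
    fit_a = DoseResponseFit(0.0, 100.0, float(rng.uniform(0.5, 2.0)),
                            float(rng.uniform(0.8, 1.5)))
    fit_b = DoseResponseFit(0.0, 100.0, float(rng.uniform(5.0, 20.0)),
                            float(rng.uniform(0.8, 1.5)))
    doses_a = np.concatenate([[0.0], fit_a.midpoint * np.logspace(-1, 1, 5)])
    doses_b = np.concatenate([[0.0], fit_b.midpoint * np.logspace(-1, 1, 5)])
    response = np.empty((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            y = _loewe_expected(da, db, fit_a, fit_b)
            if da > 0 and db > 0:
                y += config.synergy_delta
            response[i, j] = y
    matrix = DoseResponseMatrix(doses_a, doses_b, response)
    return matrix, config.synergy_delta, fit_a, fit_b
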