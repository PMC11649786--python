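"""Gene annotation parsing and the metagene coordinate system.

Transcript structures are read from GTF (1-based inclusive) and stored with
0-based half-open coordinates.  A representative (longest spliced) isoform is
chosen per gene, and genomic positions are projected onto a composite
"metagene" axis made of an upstream flank, 5'UTR, CDS, 3'UTR and a downstream
flank, each rescaled to a fixed number of bins.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationParseError",
    "TranscriptModel",
    "MetageneModel",
    "parse_annotation",
    "select_representative_transcripts",
    "build_metagene_model",
    "project_to_metagene",
]

Interval = tuple[int, int]


class AnnotationParseError(ValueError):
    """Raised for a structurally invalid annotation line."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# GTF feature names understood by the parser.  GENCODE writes "UTR"; Ensembl
# writes five_prime_utr/three_prime_utr.  Both are accepted.
_FEATURES = {"exon", "CDS", "UTR", "five_prime_utr", "three_prime_utr"}


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or adjacent half-open intervals."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class TranscriptModel:
    """One transcript with exon / CDS / UTR structure (0-based half-open)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        """0-based genomic position of the transcript's 5'-most base."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def tes(self) -> int:
        """0-based genomic position of the transcript's 3'-most base."""
        if self.strand == "+":
            return self.exons[-1][1] - 1
        return self.exons[0][0]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def region_lengths(self) -> tuple[int, int, int]:
        """Spliced lengths of (5'UTR, CDS, 3'UTR).

        Transcripts without an annotated CDS are treated as a single
        CDS-like body so they still project onto the metagene axis.
        """
        l5 = sum(e - s for s, e in self.utr5)
        lc = sum(e - s for s, e in self.cds)
        l3 = sum(e - s for s, e in self.utr3)
        if lc == 0 and l5 == 0 and l3 == 0:
            return 0, self.exon_length, 0
        return l5, lc, l3

    def to_transcript_coord(self, pos: int) -> int | None:
        """Spliced 5'->3' offset of a genomic position; None if not exonic."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                plus_offset = offset + (pos - s)
                if self.strand == "+":
                    return plus_offset
                return self.exon_length - 1 - plus_offset
            offset += e - s
        return None

    def tss_signed_distance(self, pos: int) -> int:
        """Signed genomic distance from the TSS, positive downstream."""
        d = pos - self.tss
        return d if self.strand == "+" else -d


@dataclass(frozen=True)
class MetageneModel:
    """Bin layout of the composite flank5/UTR5/CDS/UTR3/flank3 axis."""

    bins_flank5: int
    bins_utr5: int
    bins_cds: int
    bins_utr3: int
    bins_flank3: int
    flank_bp: int

    @property
    def total_bins(self) -> int:
        return (self.bins_flank5 + self.bins_utr5 + self.bins_cds
                + self.bins_utr3 + self.bins_flank3)

    @property
    def region_boundaries(self) -> tuple[int, int, int, int, int]:
        """Cumulative bin offsets after each region, strictly increasing
        ignoring empty regions."""
        b1 = self.bins_flank5
        b2 = b1 + self.bins_utr5
        b3 = b2 + self.bins_cds
        b4 = b3 + self.bins_utr3
        b5 = b4 + self.bins_flank3
        return (b1, b2, b3, b4, b5)

    def region_of(self, coord: float) -> str:
        """Name of the region band containing a metagene coordinate."""
        if not 0 <= coord < self.total_bins:
            raise ValueError(f"coordinate {coord} outside [0, {self.total_bins})")
        b1, b2, b3, b4, _ = self.region_boundaries
        if coord < b1:
            return "flank5"
        if coord < b2:
            return "utr5"
        if coord < b3:
            return "cds"
        if coord < b4:
            return "utr3"
        return "flank3"


def parse_annotation(source: str | Iterable[str]) -> list[TranscriptModel]:
    """Parse GTF text into TranscriptModel records.

    Parameters
    ----------
    source
        GTF text or an iterable of lines.  Coordinates are converted from
        1-based inclusive to 0-based half-open.  Records without a
        transcript_id attribute (e.g. gene lines) are ignored; records with
        an unknown strand symbol are rejected with a warning.

    Raises
    ------
    AnnotationParseError
        On a line with the wrong column count or non-integer coordinates.
    """
    if isinstance(source, str):
        source = source.splitlines()

    exons: dict[str, dict] = {}
    rejected: list[int] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = cols
        if feature not in _FEATURES:
            continue
        try:
            start = int(start_s) - 1  # to 0-based half-open
            end = int(end_s)
        except ValueError as exc:
            raise AnnotationParseError(
                f"line {lineno}: non-integer coordinate") from exc
        if strand not in "+-":
            rejected.append(lineno)
            continue
        attr = dict(_ATTR_RE.findall(attrs))
        tid = attr.get("transcript_id")
        if tid is None:
            continue
        rec = exons.setdefault(tid, {
            "gene_id": attr.get("gene_id", tid),
            "chrom": chrom, "strand": strand,
            "exon": [], "CDS": [], "utr5": [], "utr3": [], "UTR": [],
        })
        key = {"five_prime_utr": "utr5", "three_prime_utr": "utr3"}.get(feature, feature)
        rec[key].append((start, end))

    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} record(s) with unknown strand "
            f"(lines {rejected[:5]}{'...' if len(rejected) > 5 else ''})",
            stacklevel=2)

    models = []
    for tid, rec in exons.items():
        if not rec["exon"]:
            continue
        cds = _merge_intervals(rec["CDS"])
        utr5 = _merge_intervals(rec["utr5"])
        utr3 = _merge_intervals(rec["utr3"])
        # generic "UTR" features: side determined relative to the CDS in
        # transcript orientation
        if rec["UTR"]:
            for s, e in _merge_intervals(rec["UTR"]):
                if not cds:
                    utr5.append((s, e))
                    continue
                five_of_cds = (e <= cds[0][0]) if rec["strand"] == "+" else (s >= cds[-1][1])
                (utr5 if five_of_cds else utr3).append((s, e))
            utr5 = _merge_intervals(utr5)
            utr3 = _merge_intervals(utr3)
        models.append(TranscriptModel(
            gene_id=rec["gene_id"], transcript_id=tid,
            chrom=rec["chrom"], strand=rec["strand"],
            exons=_merge_intervals(rec["exon"]),
            cds=cds, utr5=utr5, utr3=utr3,
        ))
    return models


def select_representative_transcripts(
    models: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Pick one transcript per gene: maximal summed exon length, ties broken
    by lexicographically smallest transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key_new = (-m.exon_length, m.transcript_id)
        key_cur = (-cur.exon_length, cur.transcript_id)
        if key_new < key_cur:
            best[m.gene_id] = m
    return best


def build_metagene_model(
    bin_config: Sequence[int] = (100, 100, 100),
    flank_bp: int = 1000,
    flank_bin_bp: int = 20,
) -> MetageneModel:
    """Build the metagene bin layout.

    ``bin_config`` is either (utr5, cds, utr3) — flank bin counts are then
    derived from ``flank_bp`` at ``flank_bin_bp`` per bin — or an explicit
    5-tuple (flank5, utr5, cds, utr3, flank3).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if len(bin_config) == 3:
        if flank_bp == 0:
            nf = 0
        else:
            if flank_bin_bp <= 0 or flank_bp % flank_bin_bp:
                raise ValueError("flank_bp must be a positive multiple of flank_bin_bp")
            nf = flank_bp // flank_bin_bp
        b5, bc, b3 = bin_config
        bf5 = bf3 = nf
    elif len(bin_config) == 5:
        bf5, b5, bc, b3, bf3 = bin_config
        if flank_bp == 0:
            bf5 = bf3 = 0
    else:
        raise ValueError("bin_config must have 3 or 5 entries")
    for n in (b5, bc, b3):
        if n < 1:
            raise ValueError("region bin counts must be >= 1")
    if bf5 < 0 or bf3 < 0:
        raise ValueError("flank bin counts must be >= 0")
    if flank_bp > 0 and (bf5 == 0 or bf3 == 0):
        raise ValueError("flank bins must be >= 1 when flank_bp > 0")
    return MetageneModel(bf5, b5, bc, b3, bf3, flank_bp)


def project_to_metagene(
    position: int,
    model: TranscriptModel,
    mg: MetageneModel,
) -> float | None:
    """Project a genomic position onto the metagene axis.

    Returns a float coordinate in [0, mg.total_bins) — bin index plus
    fractional offset, 0 being the 5' end of the upstream flank — or None
    for intronic positions and positions outside flank + exons.  Minus-strand
    transcripts are mirrored so coordinate 0 is always 5'.
    """
    b1, b2, b3, b4, _ = mg.region_boundaries
    t = model.to_transcript_coord(position)
    if t is not None:
        l5, lc, l3 = model.region_lengths()
        if t < l5:
            return b1 + mg.bins_utr5 * t / l5
        if t < l5 + lc:
            return b2 + mg.bins_cds * (t - l5) / lc
        if t < l5 + lc + l3:
            return b3 + mg.bins_utr3 * (t - l5 - lc) / l3
        return None  # unreachable for consistent models

    s0, s1 = model.span
    if s0 <= position < s1:
        return None  # intron
    if mg.flank_bp == 0:
        return None
    d = model.tss_signed_distance(position)
    if d < 0:  # upstream flank
        u = -d
        if u > mg.flank_bp:
            return None
        return mg.bins_flank5 * (mg.flank_bp - u) / mg.flank_bp
    # downstream of the transcript 3' end
    if model.strand == "+":
        dd = position - s1  # 0 == first base past the transcript
    else:
        dd = s0 - 1 - position
    if dd < 0 or dd >= mg.flank_bp:
        return None
    return b4 + mg.bins_flank3 * dd / mg.flank_bp
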