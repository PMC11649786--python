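"""Metagene projection of peak sets and cross-condition relative density.

The relative-density contract: conditions share one metagene grid, each
condition's density area equals its share of the total projected-peak count,
and the areas sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import MetageneModel, TranscriptModel, project_to_metagene
from .peaks import PeakSet, annotate_peaks

__all__ = ["ProjectionResult", "DensityProfile", "project_peak_set",
           "relative_density"]


@dataclass
class ProjectionResult:
    coords: np.ndarray          # metagene coordinates, floats in [0, total)
    n_excluded: int             # peaks that could not be projected

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class DensityProfile:
    bin_centers: np.ndarray
    densities: dict[str, np.ndarray]   # condition -> per-bin density
    counts: dict[str, int]             # condition -> projected-peak count

    def area(self, condition: str) -> float:
        """Integral of one condition's density (bin width = 1)."""
        return float(np.sum(self.densities[condition]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, dens in self.densities.items():
            for center, value in zip(self.bin_centers, dens):
                rows.append((cond, center, value))
        return pd.DataFrame(rows, columns=["condition", "bin", "density"])


def project_peak_set(
    peaks: PeakSet,
    genes: Mapping[str, TranscriptModel],
    mg: MetageneModel,
    gene_subset: set | None = None,
) -> ProjectionResult:
    """Project each peak's anchor onto the metagene axis of its assigned gene.

    Peaks whose assigned gene is outside ``gene_subset`` (when given) or whose
    anchor does not project (intergenic/intronic) are counted as excluded.
    """
    ann = annotate_peaks(peaks, genes)
    coords = []
    excluded = 0
    for i, peak in enumerate(peaks.peaks):
        call = ann[i]
        gid = call.gene_id
        if gid is None or (gene_subset is not None and gid not in gene_subset):
            excluded += 1
            continue
        c = project_to_metagene(peak.anchor, genes[gid], mg)
        if c is None:
            excluded += 1
        else:
            coords.append(c)
    return ProjectionResult(np.asarray(coords, dtype=float), excluded)


def _kernel_density(coords: np.ndarray, centers: np.ndarray,
                    bandwidth: float, domain: float) -> np.ndarray:
    """Gaussian kernel sum with reflection at both domain edges."""
    x = coords[:, None]
    # reflect at 0 and at the upper edge to avoid boundary mass loss
    sources = np.concatenate([x, -x, 2 * domain - x], axis=0)
    z = (centers[None, :] - sources) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=0)
    return dens


def relative_density(
    projections: Mapping[str, ProjectionResult | np.ndarray | Sequence[float]],
    mg: MetageneModel,
    smoothing: str = "kernel",
    bandwidth: float = 5.0,
) -> DensityProfile:
    """Per-condition density on the shared metagene grid, jointly rescaled
    so condition c's area equals count_c / sum(counts) and the total area is 1.

    smoothing="histogram" gives exact per-bin relative counts;
    smoothing="kernel" applies a Gaussian kernel (bandwidth in bins) with
    edge reflection.  Areas depend only on counts, not on the smoother.
    """
    if smoothing not in ("histogram", "kernel"):
        raise ValueError(f"unknown smoothing: {smoothing!r}")
    total_bins = mg.total_bins
    centers = np.arange(total_bins) + 0.5
    arrays = {}
    for cond, proj in projections.items():
        coords = proj.coords if isinstance(proj, ProjectionResult) else np.asarray(proj, float)
        arrays[cond] = coords
    total_count = sum(len(c) for c in arrays.values())
    if total_count == 0:
        raise ValueError("no projected coordinates in any condition")

    densities: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cond, coords in arrays.items():
        counts[cond] = len(coords)
        if len(coords) == 0:
            densities[cond] = np.zeros(total_bins)
            continue
        share = len(coords) / total_count
        if smoothing == "histogram":
            hist, _ = np.histogram(coords, bins=np.arange(total_bins + 1))
            dens = hist.astype(float)
        else:
            dens = _kernel_density(coords, centers, bandwidth, float(total_bins))
        densities[cond] = dens * (share / dens.sum())
    return DensityProfile(centers, densities, counts)
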