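"""Spike-in scaling factors and signal downscaling.

Per-sample factors are computed within each batch as the ratio of the batch
minimum spike count to the sample's spike count, so the shallowest-spiked
sample keeps factor 1 and every other sample is scaled down — mirroring
read downsampling at the count/coverage level.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["compute_scaling_factors", "apply_scaling", "read_spike_table"]

REQUIRED_COLUMNS = ("sample_id", "batch", "spike_count")


def read_spike_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table missing column(s): {missing}")
    return df


def compute_scaling_factors(table: pd.DataFrame) -> dict[str, float]:
    """Per-sample scaling factors, computed within each batch.

    factor_s = min_batch(spike_count) / spike_count_s, hence in (0, 1] with
    the batch-minimum sample at exactly 1.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spike table missing column(s): {missing}")
    zeros = table.loc[table["spike_count"] <= 0, "sample_id"].tolist()
    if zeros:
        raise ValueError(
            f"cannot normalize sample(s) with zero spike-in reads: {zeros}")
    dup = table.duplicated(subset=["batch", "sample_id"])
    if dup.any():
        raise ValueError("duplicate sample_id within a batch")
    factors: dict[str, float] = {}
    for _, grp in table.groupby("batch"):
        lo = int(grp["spike_count"].min())
        for sample, count in zip(grp["sample_id"], grp["spike_count"]):
            factors[str(sample)] = lo / int(count)
    return factors


def apply_scaling(
    signal,
    factor: float,
    mode: str = "expected",
    seed: int | None = None,
):
    """Scale a count/coverage vector by a factor in (0, 1].

    mode="expected" multiplies values; mode="thinning" keeps each count unit
    independently with probability ``factor`` (binomial thinning, seeded).
    """
    if not 0 < factor <= 1:
        raise ValueError(f"scaling factor must be in (0, 1], got {factor}")
    arr = np.asarray(signal)
    if mode == "expected":
        return arr * factor
    if mode == "thinning":
        if factor == 1.0:
            return arr.copy()
        counts = np.asarray(signal)
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("thinning requires integer counts")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("thinning requires non-negative counts")
        rng = np.random.default_rng(seed)
        return rng.binomial(counts, factor)
    raise ValueError(f"unknown mode: {mode!r}")


def factors_frame(factors: Mapping[str, float]) -> pd.DataFrame:
    """Scaling factors as a two-column frame for TSV output."""
    return pd.DataFrame(
        {"sample_id": list(factors), "factor": list(factors.values())})
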