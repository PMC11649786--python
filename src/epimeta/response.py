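"""Kinetic and pharmacological response models.

One-phase exponential decay fits for mRNA half-life, four-parameter
log-logistic (4PL) monotherapy dose-response fits, and scoring of two-drug
combination matrices against the Loewe additivity reference
d1/D1(y) + d2/D2(y) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecayFit", "DoseResponseFit", "DoseResponseMatrix", "SynergyResult",
    "fit_decay", "fit_dose_response", "loewe_reference",
    "synergy_score_and_classify",
]

#: classification thresholds on the overall synergy score (percentage points)
SYNERGY_THRESHOLD = 10.0
BISECTION_TOL = 1e-6
BISECTION_MAX_ITER = 200


@dataclass
class DecayFit:
    k: float                 # decay rate constant, per hour
    t_half: float            # ln2 / k; inf when not decaying
    n0: float                # fitted abundance at t = 0
    decaying: bool           # False when the fitted k <= 0


def fit_decay(times, abundances) -> DecayFit:
    """Least-squares fit of N(t) = N0 * exp(-k t).

    Initialized from the log-linear regression slope; the half-life is
    ln 2 / k.  Non-decaying data (fitted k <= 0) yields a flagged result
    with t_half = inf.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and abundances must be 1-D and equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(y <= 0):
        raise ValueError("abundances must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    slope, intercept = np.polyfit(t, np.log(y), 1)
    k0, n0_0 = -slope, math.exp(intercept)
    try:
        popt, _ = curve_fit(
            lambda tt, n0, k: n0 * np.exp(-k * tt), t, y,
            p0=[n0_0, k0 if k0 > 0 else 1e-3], maxfev=10_000)
        n0, k = float(popt[0]), float(popt[1])
    except RuntimeError:
        n0, k = n0_0, k0
    if k <= 0:
        return DecayFit(k=k, t_half=math.inf, n0=n0, decaying=False)
    return DecayFit(k=k, t_half=math.log(2) / k, n0=n0, decaying=True)


def _ll4(d, floor, ceiling, midpoint, slope):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (midpoint / np.where(d > 0, d, 1.0)) ** slope,
                         np.inf)
    return floor + (ceiling - floor) / (1.0 + ratio)


@dataclass
class DoseResponseFit:
    """4PL log-logistic curve y(d) = floor + (ceiling-floor)/(1+(mid/d)^slope)."""

    floor: float
    ceiling: float
    midpoint: float
    slope: float
    degenerate: bool = False

    def __call__(self, dose) -> np.ndarray | float:
        out = _ll4(dose, self.floor, self.ceiling, self.midpoint, self.slope)
        return float(out) if np.isscalar(dose) else out

    def inverse(self, response: float) -> float:
        """Dose producing a given response; defined on (floor, ceiling)."""
        r = (response - self.floor) / (self.ceiling - self.floor)
        if not 0 < r < 1:
            raise ValueError(f"response {response} outside the open range "
                             f"({self.floor}, {self.ceiling})")
        return self.midpoint * (r / (1 - r)) ** (1 / self.slope)


def fit_dose_response(doses, responses) -> DoseResponseFit:
    """Least-squares 4PL fit of a monotherapy inhibition curve."""
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct doses")
    if 0 not in d:
        raise ValueError("dose grid must include 0")
    if np.ptp(y) < 1e-9:
        return DoseResponseFit(float(y.mean()), float(y.mean()), 1.0, 1.0,
                               degenerate=True)
    pos = d[d > 0]
    p0 = [float(y.min()), float(y.max()),
          float(np.exp(np.mean(np.log(pos)))), 1.0]
    bounds = ([-np.inf, -np.inf, 1e-12, 1e-3],
              [np.inf, np.inf, np.inf, 50.0])
    popt, _ = curve_fit(_ll4, d, y, p0=p0, bounds=bounds, maxfev=20_000)
    return DoseResponseFit(*map(float, popt))


@dataclass
class DoseResponseMatrix:
    """Inhibition readings over a complete two-drug dose grid.

    Rows follow doses_a, columns doses_b; the dose-0 row/column are the two
    monotherapies and the (0, 0) cell is the untreated control.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    response: np.ndarray   # inhibition %, shape (len(doses_a), len(doses_b))

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("response shape does not match the dose grids")
        if 0 not in self.doses_a or 0 not in self.doses_b:
            raise ValueError("both dose grids must include 0")

    @classmethod
    def from_viability_frame(cls, frame: pd.DataFrame,
                             viability: bool = True) -> "DoseResponseMatrix":
        """Build from a TSV-style frame: index = doses_a, columns = doses_b,
        body = viability % (converted to inhibition = 100 - viability) or
        inhibition % directly when ``viability=False``."""
        doses_a = frame.index.to_numpy(dtype=float)
        doses_b = frame.columns.to_numpy(dtype=float)
        body = frame.to_numpy(dtype=float)
        if viability:
            body = 100.0 - body
        return cls(doses_a, doses_b, body)

    def monotherapy_a(self) -> tuple[np.ndarray, np.ndarray]:
        j = int(np.where(self.doses_b == 0)[0][0])
        return self.doses_a, self.response[:, j]

    def monotherapy_b(self) -> tuple[np.ndarray, np.ndarray]:
        i = int(np.where(self.doses_a == 0)[0][0])
        return self.doses_b, self.response[i, :]


def _bisect_isobole(da: float, db: float, fit_a: DoseResponseFit,
                    fit_b: DoseResponseFit) -> float:
    """Solve da/Da(y) + db/Db(y) = 1 for y by bisection; NaN if no root lies
    in the overlap of the two curves' open response ranges."""
    lo = max(fit_a.floor, fit_b.floor)
    hi = min(fit_a.ceiling, fit_b.ceiling)
    if not lo < hi:
        return math.nan
    eps = 1e-9 * (hi - lo)
    lo_y, hi_y = lo + eps, hi - eps

    def f(y: float) -> float:
        total = 0.0
        for dose, fit in ((da, fit_a), (db, fit_b)):
            if dose > 0:
                total += dose / fit.inverse(y)
        return total - 1.0

    f_lo, f_hi = f(lo_y), f(hi_y)
    if f_lo < 0 or f_hi > 0:
        return math.nan  # expected response outside both invertible ranges
    for _ in range(BISECTION_MAX_ITER):
        mid = 0.5 * (lo_y + hi_y)
        if f(mid) > 0:
            lo_y = mid
        else:
            hi_y = mid
        if hi_y - lo_y < BISECTION_TOL:
            break
    return 0.5 * (lo_y + hi_y)


def loewe_reference(
    matrix: DoseResponseMatrix,
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
) -> np.ndarray:
    """Expected inhibition for every cell under Loewe additivity.

    Monotherapy edges reduce to the corresponding fitted curve; combination
    cells solve the isobole equation by bisection.  Cells with no solution
    in the curves' shared response range are NaN.
    """
    if fit_a.degenerate or fit_b.degenerate:
        raise ValueError("cannot build a Loewe reference from a degenerate fit")
    expected = np.empty_like(matrix.response)
    for i, da in enumerate(matrix.doses_a):
        for j, db in enumerate(matrix.doses_b):
            if db == 0:
                expected[i, j] = fit_a(da)
            elif da == 0:
                expected[i, j] = fit_b(db)
            else:
                expected[i, j] = _bisect_isobole(da, db, fit_a, fit_b)
    return expected


@dataclass
class SynergyResult:
    excess: np.ndarray          # observed - expected; NaN on monotherapy cells
    score: float                # mean excess over defined combination cells
    classification: str         # synergistic | additive | antagonistic
    n_defined: int


def synergy_score_and_classify(
    matrix: DoseResponseMatrix,
    expected: np.ndarray,
) -> SynergyResult:
    """Per-cell excess over the Loewe reference and the overall score.

    The overall score is the mean excess over defined combination cells
    (monotherapy rows/columns excluded); classification uses the printed
    thresholds: > 10 synergistic, < -10 antagonistic, else additive.
    """
    combo = np.outer(matrix.doses_a > 0, matrix.doses_b > 0)
    defined = combo & ~np.isnan(expected)
    if not defined.any():
        raise ValueError("no defined combination cells")
    excess = np.where(combo, matrix.response - expected, np.nan)
    score = float(np.nanmean(excess[defined]))
    if score > SYNERGY_THRESHOLD:
        cls = "synergistic"
    elif score < -SYNERGY_THRESHOLD:
        cls = "antagonistic"
    else:
        cls = "additive"
    return SynergyResult(excess, score, cls, int(defined.sum()))
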