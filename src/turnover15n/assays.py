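"""Growth-curve and qPCR arithmetic: Beer-Lambert OD, exponential rate
constants, moving averages, two-sample t-tests, and spike-in / 5S-normalized
delta-delta-CT quantification.

Sign convention for CT differences: dCT = CT(reference) - CT(target), so a
larger dCT means *more* target (each PCR cycle is a two-fold difference).
ddCT = dCT(stress) - dCT(normal), and the fold change is 2**ddCT: negative
ddCT means the target decreased under stress.  Note this follows the
spike-in-minus-target convention used for tRNA quantification; much of the
qPCR literature defines dCT with the opposite sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "od_from_intensity",
    "moving_average",
    "growth_rate",
    "auto_growth_window",
    "compare_rates",
    "ddct",
]

#: validated linear range of the OD measurement device
OD_LINEAR_RANGE = (0.0, 0.45)


@dataclass(frozen=True)
class GrowthCurve:
    """An OD635 time series (minutes); times strictly increasing."""

    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def od_from_intensity(intensity, blank_intensity) -> np.ndarray | float:
    """Beer-Lambert optical density from transmitted light intensity.

    OD = log10(I_blank / I): zero for a blank, 1 when the sample transmits a
    tenth of the blank intensity.
    """
    i = np.asarray(intensity, dtype=float)
    if np.any(i <= 0) or blank_intensity <= 0:
        raise ValueError("intensities must be positive")
    out = np.log10(blank_intensity / i)
    return float(out) if out.ndim == 0 else out


def moving_average(
    times: Sequence[float], values: Sequence[float], window_minutes: float
) -> np.ndarray:
    """Centered moving average over a time window; edges use available points."""
    if window_minutes <= 0:
        raise ValueError("window must be positive")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    half = window_minutes / 2.0
    out = np.empty_like(v)
    for i, ti in enumerate(t):
        sel = (t >= ti - half) & (t <= ti + half)
        out[i] = v[sel].mean()
    return out


def growth_rate(
    curve: GrowthCurve,
    fit_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Exponential growth rate constant k (per minute) from ln(OD) vs time.

    OLS slope of ln(OD) against time within ``fit_window`` (whole curve when
    None); a negative k indicates net cell death.  Non-positive OD points in
    the window are dropped.  Returns ``(k, stderr)``.
    """
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    if fit_window is not None:
        sel = (t >= fit_window[0]) & (t <= fit_window[1])
        t, od = t[sel], od[sel]
    pos = od > 0
    t, od = t[pos], od[pos]
    if t.size < 3:
        raise ValueError("need >= 3 points with OD > 0 in the fit window")
    res = stats.linregress(t, np.log(od))
    return float(res.slope), float(res.stderr)


def auto_growth_window(
    curve: GrowthCurve, window_minutes: float, step: int = 1
) -> tuple[float, float]:
    """Sliding window of the given width maximizing the ln(OD)-vs-t R^2,
    breaking near-ties (R^2 within 1e-6) toward the steepest slope so that
    a flat-but-linear arrest segment never outranks the growth phase.

    A convenience for unattended fitting; explicit windows are preferred
    when the experiment defines one.
    """
    t = np.asarray(curve.times, dtype=float)
    best: tuple[float, float, tuple[float, float]] | None = None
    for i in range(0, len(t), step):
        lo = t[i]
        hi = lo + window_minutes
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 3:
            continue
        od = np.asarray(curve.od, dtype=float)[sel]
        if np.any(od <= 0):
            continue
        res = stats.linregress(t[sel], np.log(od))
        key = (round(res.rvalue**2, 6), res.slope)
        if best is None or key > (best[0], best[1]):
            best = (key[0], key[1], (lo, hi))
    if best is None:
        raise ValueError("no window with >= 3 positive-OD points")
    return best[2]


def compare_rates(
    rates_a: Sequence[float], rates_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-tailed two-sample t-test on replicate growth rate constants.

    Equal-variance Student's t by default, Welch's t behind the flag.
    Degenerate inputs (zero variance in both groups with equal means) give
    ``(nan, nan)`` rather than raising.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return math.nan, math.nan
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    cond_stress: str,
    cond_normal: str,
) -> tuple[float, float]:
    """Delta-delta-CT relative quantification of one target.

    ``table`` needs columns ``target_id``, ``condition``, ``ct`` (replicate
    rows are averaged).  With dCT = CT(reference) - CT(target) per condition,
    ddCT = dCT(stress) - dCT(normal) and fold change = 2**ddCT; ddCT of -1
    means the target halved under stress.  A missing (target, condition)
    cell raises with the cell named.
    """
    required = {"target_id", "condition", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if np.any(table["ct"] <= 0):
        raise ValueError("CT values must be positive")

    def _ct(tid: str, cond: str) -> float:
        sel = table[(table["target_id"] == tid) & (table["condition"] == cond)]
        if sel.empty:
            raise ValueError(f"missing CT cell: target={tid!r}, condition={cond!r}")
        return float(sel["ct"].mean())

    dct_stress = _ct(reference, cond_stress) - _ct(target, cond_stress)
    dct_normal = _ct(reference, cond_normal) - _ct(target, cond_normal)
    ddct_val = dct_stress - dct_normal
    return ddct_val, 2.0**ddct_val
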