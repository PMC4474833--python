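"""Protein turnover kinetics from 15N pulse-labeling ratio series.

After cells switch from light (14N) to heavy (15N) medium at t0, pre-existing
protein decays exponentially while new protein is synthesized.  For a
steady-state proteome (k_deg = k_syn) the measured light/heavy ratio
R(t) = N14/N15 obeys

    1 + 1/R = exp(k_syn * (t - t0)),

so Y = ln(1 + 1/R) is linear in time with slope k_syn, and the half-life of
the pre-existing pool is T = ln 2 / k_syn.  Fits with an insignificant slope
(P > 0.05) correspond to half-lives that cannot be distinguished from
"longer than 500 min" and are reported as censored at that cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RatioSeries",
    "TurnoverEstimate",
    "y_transform",
    "fit_ksyn",
    "fit_many",
    "proteome_trend",
    "half_life_stats",
    "compare_half_life_distributions",
    "HALF_LIFE_CAP_MIN",
    "P_CENSOR",
]

#: half-lives above this cap cannot be reliably resolved by the linear fit
HALF_LIFE_CAP_MIN = 500.0
#: fits with correlation P above this are censored
P_CENSOR = 0.05


@dataclass(frozen=True)
class RatioSeries:
    """Measured 14N/15N ratios of one protein over labeling time (minutes)."""

    protein_id: str
    times: tuple[float, ...]
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.ratios):
            raise ValueError("times and ratios must have equal length")
        if any(t <= 0 for t in self.times):
            raise ValueError("labeling times must be > 0 (minutes after t0)")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TurnoverEstimate:
    """Per-protein fit: synthesis rate constant, fit quality, half-life."""

    protein_id: str
    k_syn: float  # per minute
    intercept: float
    pearson_r: float
    p_value: float
    half_life: float  # minutes; inf when k_syn <= 0
    censored: bool
    n_points: int
    reason: str | None = None


def y_transform(ratio):
    """Y = ln(1 + 1/R); strictly decreasing in R, Y -> 0 as R -> inf."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratio must be positive")
    out = np.log1p(1.0 / r)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def fit_ksyn(
    series: RatioSeries,
    min_points: int = 3,
    through_origin: bool = False,
    half_life_cap: float = HALF_LIFE_CAP_MIN,
    p_censor: float = P_CENSOR,
) -> TurnoverEstimate:
    """Fit the synthesis rate constant of one protein.

    Ordinary least squares of Y = ln(1 + 1/R) on t; the slope is k_syn and
    the fit significance is the two-sided P of the Pearson correlation
    (t-distributed with n-2 df).  ``through_origin`` forces the zero
    intercept of the idealized model; the default free intercept absorbs any
    labeling lag.  The estimate is censored when the half-life exceeds
    ``half_life_cap`` or the fit is insignificant (P > ``p_censor``).

    With fewer than ``min_points`` points the estimate is withheld
    (NaN fields, ``reason`` set) rather than raised.
    """
    n = len(series)
    if n < min_points:
        return TurnoverEstimate(
            series.protein_id,
            k_syn=math.nan,
            intercept=math.nan,
            pearson_r=math.nan,
            p_value=math.nan,
            half_life=math.nan,
            censored=True,
            n_points=n,
            reason=f"fewer than {min_points} points",
        )
    t = np.asarray(series.times, dtype=float)
    y = y_transform(np.asarray(series.ratios, dtype=float))

    if through_origin:
        slope = float(t @ y / (t @ t))
        intercept = 0.0
    else:
        slope_i = stats.linregress(t, y)
        slope, intercept = float(slope_i.slope), float(slope_i.intercept)

    if np.allclose(y, y[0]):
        # degenerate flat series: correlation undefined, slope 0
        r_val, p_val = 0.0, 1.0
    else:
        r_val, p_val = stats.pearsonr(t, y)
        r_val, p_val = float(r_val), float(p_val)

    half_life = math.inf if slope <= 0 else math.log(2.0) / slope
    censored = (half_life > half_life_cap) or (p_val > p_censor)
    return TurnoverEstimate(
        series.protein_id,
        k_syn=slope,
        intercept=intercept,
        pearson_r=r_val,
        p_value=p_val,
        half_life=half_life,
        censored=censored,
        n_points=n,
    )


def fit_many(
    series: Iterable[RatioSeries], min_points: int = 3, **kwargs
) -> list[TurnoverEstimate]:
    return [fit_ksyn(s, min_points=min_points, **kwargs) for s in series]


def proteome_trend(
    series: Sequence[RatioSeries], aggregator: str = "median"
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Proteome-wide ratio trend over labeling time.

    Aggregates the protein-level ratio per timepoint (median by default,
    mean optional), fits the aggregate against time and returns
    ``(times, aggregated_ratios, pearson_r, p_value)``.  Requires data at
    three or more distinct timepoints.
    """
    agg_fn = {"median": np.median, "mean": np.mean}.get(aggregator)
    if agg_fn is None:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    by_time: dict[float, list[float]] = {}
    for s in series:
        for t, r in zip(s.times, s.ratios):
            by_time.setdefault(t, []).append(r)
    if len(by_time) < 3:
        raise ValueError("need data at >= 3 timepoints")
    times = np.array(sorted(by_time))
    agg = np.array([agg_fn(by_time[t]) for t in times])
    r_val, p_val = stats.pearsonr(times, agg)
    return times, agg, float(r_val), float(p_val)


def half_life_stats(
    estimates: Sequence[TurnoverEstimate],
    fast_threshold: float = 100.0,
    cap: float = HALF_LIFE_CAP_MIN,
    mean_includes_censored: bool = False,
    bins: Sequence[float] | None = None,
) -> dict:
    """Cohort half-life summary.

    Censored proteins are counted in the ">cap" bin; the mean is computed
    over uncensored half-lives unless ``mean_includes_censored``, in which
    case censored proteins enter at the cap.  Returns mean, fraction below
    ``fast_threshold``, fraction censored above ``cap``, and a histogram of
    capped half-lives.
    """
    usable = [e for e in estimates if not math.isnan(e.k_syn)]
    if not usable:
        raise ValueError("no usable estimates")
    capped = np.array(
        [cap if (e.censored or e.half_life > cap) else e.half_life for e in usable]
    )
    censored_mask = np.array(
        [(e.censored or e.half_life > cap) for e in usable], dtype=bool
    )
    uncensored = capped[~censored_mask]
    if mean_includes_censored:
        mean_hl = float(capped.mean())
    else:
        mean_hl = float(uncensored.mean()) if uncensored.size else math.nan
    if bins is None:
        bins = np.linspace(0.0, cap, 21)
    hist, edges = np.histogram(capped, bins=bins)
    return {
        "n": len(usable),
        "mean_half_life": mean_hl,
        "fraction_below": float((capped < fast_threshold).mean()),
        "fraction_censored": float(censored_mask.mean()),
        "hist_counts": hist,
        "hist_edges": edges,
    }


def compare_half_life_distributions(
    a: Sequence[TurnoverEstimate] | Sequence[float],
    b: Sequence[TurnoverEstimate] | Sequence[float],
    cap: float = HALF_LIFE_CAP_MIN,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of half-life distributions.

    Censored half-lives enter at the cap.  Returns ``(D, p_value)``.
    """

    def _values(group):
        vals = []
        for e in group:
            if isinstance(e, TurnoverEstimate):
                if math.isnan(e.k_syn):
                    continue
                vals.append(cap if (e.censored or e.half_life > cap) else e.half_life)
            else:
                vals.append(min(float(e), cap))
        return np.asarray(vals)

    va, vb = _values(a), _values(b)
    if va.size == 0 or vb.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(va, vb, method="asymp")
    return float(res.statistic), float(res.pvalue)
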