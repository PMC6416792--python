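"""Temperature response of minimum conductance: Arrhenius analysis.

Cuticular permeation is a kinetic process, so ln(g_min) against 1/T (K) is
expected to be linear with slope -E_p/R.  A change of slope at some
transition temperature indicates that additional permeation pathways open
up — the signature of thermally induced defects in the wax barrier.  This
module transforms (temperature, g_min) data to Arrhenius coordinates, fits
single and two-segment (biphasic) lines, locates the transition temperature
as the intersection of the two segments, converts the high-temperature slope
into an activation energy, and provides the accompanying statistical tests
(Spearman trend, Shapiro-Wilk-gated Welch t / Mann-Whitney comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .psychro import GAS_CONSTANT, KELVIN_OFFSET

__all__ = [
    "TemperatureSeries",
    "ArrheniusSegment",
    "ArrheniusResult",
    "ThermalError",
    "arrhenius_points",
    "fit_segment",
    "fit_biphasic",
    "activation_energy",
    "temperature_trend_test",
    "compare_groups",
]


class ThermalError(ValueError):
    pass


@dataclass(frozen=True)
class TemperatureSeries:
    """Replicate g_min values (m s-1) at each air temperature (degC)."""

    species: str
    entries: tuple  # of (t_air, tuple of g_min replicates)

    def __post_init__(self) -> None:
        entries = tuple(
            (float(t), tuple(float(g) for g in reps)) for t, reps in self.entries
        )
        object.__setattr__(self, "entries", entries)
        if len(entries) < 2:
            raise ThermalError("need at least 2 temperature levels")
        for t, reps in entries:
            if not reps:
                raise ThermalError(f"no replicates at {t} degC")
            if any(g <= 0 for g in reps):
                raise ThermalError(f"non-positive g_min at {t} degC")

    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])

    def means(self) -> np.ndarray:
        return np.array([np.mean(r) for _, r in self.entries])

    def replicate_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (temperature, g_min) arrays over all replicates."""
        ts, gs = [], []
        for t, reps in self.entries:
            ts.extend([t] * len(reps))
            gs.extend(reps)
        return np.array(ts), np.array(gs)


@dataclass(frozen=True)
class ArrheniusSegment:
    """One fitted line in (1/T_K, ln g) coordinates."""

    slope: float      # K
    intercept: float  # ln(m s-1)
    r2: float
    p_slope: float    # two-sided p for slope != 0
    t_range: tuple    # (degC, degC), ordered
    n: int


@dataclass(frozen=True)
class ArrheniusResult:
    segments: tuple            # 1 or 2 ArrheniusSegment, low-T first
    transition_temp: float | None   # degC, present iff 2 segments
    activation_energy: float | None  # kJ mol-1, from the high-T segment
    f_stat: float | None = None
    f_pvalue: float | None = None

    @property
    def biphasic(self) -> bool:
        return len(self.segments) == 2


def arrhenius_points(
    series: TemperatureSeries, use: Literal["mean", "replicates"] = "mean"
) -> np.ndarray:
    """Transform to Arrhenius coordinates: rows of (1/T_K, ln g_min).

    ``use='mean'`` takes per-temperature means of the replicates (one point
    per temperature level); ``use='replicates'`` keeps every replicate.
    Rows are ordered by increasing temperature (decreasing 1/T).
    """
    if use == "mean":
        t, g = series.temperatures(), series.means()
    elif use == "replicates":
        t, g = series.replicate_pairs()
    else:
        raise ThermalError(f"unknown mode {use!r}")
    order = np.argsort(t, kind="stable")
    t, g = t[order], g[order]
    return np.column_stack([1.0 / (t + KELVIN_OFFSET), np.log(g)])


def _t_of(x: float) -> float:
    return 1.0 / x - KELVIN_OFFSET


def fit_segment(points: np.ndarray) -> ArrheniusSegment:
    """Ordinary least squares of ln g on 1/T for one temperature range."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ThermalError("need >= 2 Arrhenius points")
    x, y = points[:, 0], points[:, 1]
    if np.ptp(x) == 0:
        raise ThermalError("zero variance in 1/T")
    if len(x) == 2:
        # exact interpolating line; no residual dof for a p-value
        slope = (y[1] - y[0]) / (x[1] - x[0])
        icpt = y[0] - slope * x[0]
        return ArrheniusSegment(
            slope=float(slope), intercept=float(icpt), r2=1.0,
            p_slope=float("nan"),
            t_range=(min(map(_t_of, x)), max(map(_t_of, x))), n=2,
        )
    res = stats.linregress(x, y)
    return ArrheniusSegment(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        t_range=(float(min(map(_t_of, x))), float(max(map(_t_of, x)))),
        n=len(x),
    )


def _segment_rss(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    seg = fit_segment(points)
    return float(np.sum((y - (seg.intercept + seg.slope * x)) ** 2))


def fit_biphasic(
    points: np.ndarray,
    alpha: float = 0.05,
    min_per_segment: int = 2,
    force_split: bool = False,
) -> ArrheniusResult:
    """Single-line vs two-segment Arrhenius fit with breakpoint search.

    All contiguous splits (in temperature order) with at least
    ``min_per_segment`` points per side are evaluated; the split minimising
    total RSS is the biphasic candidate.  It is adopted over the single line
    when an F-test on the RSS reduction (2 extra parameters) is significant
    at ``alpha`` after Bonferroni correction for the number of candidate
    splits — the correction compensates the selection of the best split,
    keeping the empirical false-positive rate near ``alpha``.

    The transition temperature is the intersection abscissa of the two
    fitted lines (converted to degC) and the activation energy comes from
    the high-temperature segment, E_p = -slope * R.  ``force_split=True``
    returns the best two-segment candidate regardless of the F-test
    (parameter-recovery experiments on data known to be biphasic).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2 * min_per_segment + 1 or n < 5:
        raise ThermalError(
            f"need >= {max(5, 2 * min_per_segment + 1)} points for a "
            f"biphasic fit, got {n}"
        )
    # order by increasing temperature = decreasing 1/T
    points = points[np.argsort(-points[:, 0], kind="stable")]
    single = fit_segment(points)
    rss1 = _segment_rss(points)

    best = None
    n_splits = 0
    for k in range(min_per_segment, n - min_per_segment + 1):
        n_splits += 1
        lo, hi = points[:k], points[k:]
        try:
            rss2 = _segment_rss(lo) + _segment_rss(hi)
        except ThermalError:  # zero x-variance on one side (ties)
            continue
        if best is None or rss2 < best[0] - 1e-18:
            best = (rss2, k)
    if best is None:
        raise ThermalError("no admissible split")
    rss2, k = best
    df2 = n - 4
    if df2 > 0 and rss2 > 0:
        f_stat = ((rss1 - rss2) / 2.0) / (rss2 / df2)
        f_p = float(stats.f.sf(f_stat, 2, df2))
    else:
        f_stat, f_p = float("inf"), 0.0
    adopt = force_split or (f_p < alpha / n_splits)
    if not adopt:
        return ArrheniusResult(
            segments=(single,),
            transition_temp=None,
            activation_energy=None,
            f_stat=float(f_stat),
            f_pvalue=f_p,
        )
    low_seg = fit_segment(points[:k])
    high_seg = fit_segment(points[k:])
    if low_seg.slope == high_seg.slope:
        raise ThermalError("parallel segments: no intersection")
    x_int = (high_seg.intercept - low_seg.intercept) / (
        low_seg.slope - high_seg.slope
    )
    return ArrheniusResult(
        segments=(low_seg, high_seg),
        transition_temp=float(_t_of(x_int)),
        activation_energy=activation_energy(high_seg.slope),
        f_stat=float(f_stat),
        f_pvalue=f_p,
    )


def activation_energy(slope: float) -> float:
    """Activation energy E_p = -slope * R (kJ mol-1) from an Arrhenius slope (K)."""
    if not np.isfinite(slope):
        raise ThermalError("slope must be finite")
    return -float(slope) * GAS_CONSTANT / 1000.0


def temperature_trend_test(series: TemperatureSeries) -> dict:
    """Spearman rank correlation of g_min with temperature (replicate level)."""
    t, g = series.replicate_pairs()
    if len(t) < 3:
        raise ThermalError("need >= 3 (temperature, g_min) pairs")
    if np.ptp(g) == 0 or np.ptp(t) == 0:
        raise ThermalError("constant input: correlation undefined")
    rho, p = stats.spearmanr(t, g)
    return {"rho": float(rho), "p": float(p), "n": int(len(t))}


def compare_groups(a: Sequence[float], b: Sequence[float],
                   normality_alpha: float = 0.05) -> dict:
    """Two-sample location comparison with a normality gate.

    Shapiro-Wilk on each group; if both are compatible with normality the
    groups are compared by Welch's t-test, otherwise by the Mann-Whitney U.
    Returns test name, statistic, p, and the per-group Shapiro p-values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ThermalError("each group needs n >= 3")
    # identical-sample degenerate case: no evidence of difference
    if np.array_equal(a, b):
        return {"test": "welch-t", "statistic": 0.0, "p": 1.0,
                "shapiro_p": (float("nan"), float("nan"))}
    pa = float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
    pb = float(stats.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
    if pa > normality_alpha and pb > normality_alpha:
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "welch-t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney-u"
    return {"test": name, "statistic": float(res.statistic),
            "p": float(res.pvalue), "shapiro_p": (pa, pb)}
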