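"""Leaf drying-curve kinetics and minimum-conductance extraction.

A detached, petiole-sealed leaf drying over silica gel first transpires
through closing stomata; once the stomata are maximally closed, water can
leave only across the cuticle and the conductance settles on a low plateau,
the minimum leaf conductance g_min.  The pipeline is

    weight series -> relative water deficit (RWD)
                  -> transpiration flux J = dFW / (dt * A)
                  -> conductance g = J / driving force
                  -> two-segment fit of g(RWD): decline + plateau

The breakpoint of the two-segment fit is the RWD at maximum stomatal closure
(RWD_SC, the abscissa where the declining segment meets the plateau) and the
plateau level is g_min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .psychro import VaporConditions, driving_force

__all__ = [
    "LeafSpecimen",
    "DryingObservation",
    "FluxInterval",
    "ConductancePoint",
    "GminResult",
    "DryingError",
    "PlateauOnlyError",
    "InsufficientPlateauError",
    "relative_water_deficit",
    "morphology_traits",
    "transpiration_series",
    "interval_driving_forces",
    "conductance_series",
    "fit_drying_curve",
]

# Balance noise can push RWD slightly outside [0, 1]; clip within this band,
# error beyond it.
_RWD_SLACK = 0.02


class DryingError(ValueError):
    pass


class PlateauOnlyError(DryingError):
    """All points statistically flat: no stomatal decline to intersect."""


class InsufficientPlateauError(DryingError):
    """Fewer than the minimum number of points on the conductance plateau."""


@dataclass(frozen=True)
class LeafSpecimen:
    """Morphology of one leaf (or leaflet).

    ``projected_area_total`` is the sum of the adaxial and abaxial projected
    surfaces (m2); transpiration fluxes are normalised by it.  The one-sided
    area (total / 2) is used for leaf mass per area.
    """

    species: str
    saturated_weight: float  # g
    dry_weight: float        # g
    projected_area_total: float  # m2

    def __post_init__(self) -> None:
        if not 0 < self.dry_weight < self.saturated_weight:
            raise DryingError(
                f"need 0 < dry_weight < saturated_weight, got "
                f"dry={self.dry_weight}, sat={self.saturated_weight}"
            )
        if self.projected_area_total <= 0:
            raise DryingError("projected_area_total must be positive")

    @property
    def one_sided_area(self) -> float:
        return self.projected_area_total / 2.0

    @property
    def water_capacity(self) -> float:
        """Saturated minus dry weight (g)."""
        return self.saturated_weight - self.dry_weight


@dataclass(frozen=True)
class DryingObservation:
    """One balance reading during a drying run."""

    time: float          # s since start
    fresh_weight: float  # g
    air_temp: float      # degC
    leaf_temp: float | None = None  # degC, logged intermittently


@dataclass(frozen=True)
class FluxInterval:
    """Transpiration flux over one interval between consecutive weighings."""

    t_mid: float      # s
    j: float          # g m-2 s-1
    w_mid: float      # g, midpoint fresh weight
    flagged: bool = False  # weight gain (J < 0), kept but marked


@dataclass(frozen=True)
class ConductancePoint:
    rwd: float    # dimensionless
    g: float      # m s-1
    j: float      # g m-2 s-1
    t_mid: float  # s


@dataclass(frozen=True)
class GminResult:
    """Two-segment fit of a conductance-RWD drying curve."""

    g_min: float          # m s-1, plateau level
    rwd_sc: float         # RWD at maximum stomatal closure
    plateau_points: int
    decline_slope: float  # conductance per unit RWD (negative)
    fit_rss: float


def relative_water_deficit(actual, specimen: LeafSpecimen):
    """RWD = 1 - (actual - dry) / (saturated - dry).

    0 at full hydration, 1 at full desiccation.  Values within 2 % outside
    [0, 1] (balance noise) are clipped with a warning; beyond that an error
    is raised.  Accepts scalars or arrays.
    """
    if specimen.water_capacity <= 0:
        raise DryingError("degenerate specimen: saturated_weight == dry_weight")
    actual = np.asarray(actual, dtype=float)
    rwd = 1.0 - (actual - specimen.dry_weight) / specimen.water_capacity
    if np.any(rwd < -_RWD_SLACK) or np.any(rwd > 1.0 + _RWD_SLACK):
        raise DryingError(
            f"RWD outside [-{_RWD_SLACK}, {1 + _RWD_SLACK}]: "
            f"range [{rwd.min():.4f}, {rwd.max():.4f}]"
        )
    if np.any(rwd < 0) or np.any(rwd > 1):
        warnings.warn("RWD clipped to [0, 1] (balance noise)", stacklevel=2)
        rwd = np.clip(rwd, 0.0, 1.0)
    return rwd if rwd.ndim else float(rwd)


def morphology_traits(specimen: LeafSpecimen) -> dict:
    """Leaf mass per area (g m-2, one-sided) and leaf water content (g g-1)."""
    return {
        "lma": specimen.dry_weight / specimen.one_sided_area,
        "lwc": specimen.water_capacity / specimen.saturated_weight,
    }


def _check_times(times: np.ndarray) -> None:
    if np.any(times < 0):
        raise DryingError("negative timestamps")
    dt = np.diff(times)
    if np.any(dt == 0):
        raise DryingError("duplicate timestamps")
    if np.any(dt < 0):
        raise DryingError("timestamps must be strictly increasing")


def transpiration_series(
    obs: Sequence[DryingObservation], specimen: LeafSpecimen
) -> list[FluxInterval]:
    """Per-interval transpiration flux J = dFW / (dt * A).

    ``A`` is the total (two-sided) projected area.  Each flux is reported at
    the interval midpoint; intervals where the balance recorded a weight
    gain yield J < 0 and are passed through with ``flagged=True``.
    """
    if len(obs) < 2:
        raise DryingError("need at least 2 observations")
    t = np.array([o.time for o in obs], dtype=float)
    w = np.array([o.fresh_weight for o in obs], dtype=float)
    _check_times(t)
    dw = -np.diff(w)  # positive for weight loss
    dt = np.diff(t)
    j = dw / (dt * specimen.projected_area_total)
    return [
        FluxInterval(
            t_mid=float((t[i] + t[i + 1]) / 2),
            j=float(j[i]),
            w_mid=float((w[i] + w[i + 1]) / 2),
            flagged=bool(j[i] < 0),
        )
        for i in range(len(j))
    ]


def interval_driving_forces(
    obs: Sequence[DryingObservation],
    a_apo: float = 1.0,
    a_air: float = 0.0,
    leaf_air_offset: float = 0.0,
) -> np.ndarray:
    """Driving force (g m-3) for each interval between consecutive readings.

    Leaf temperature is taken from the intermittent IR loggings, linearly
    interpolated to interval midpoints; where no leaf temperature was logged
    at all, air temperature plus ``leaf_air_offset`` is used.
    """
    t = np.array([o.time for o in obs], dtype=float)
    t_air = np.array([o.air_temp for o in obs], dtype=float)
    t_mid = (t[:-1] + t[1:]) / 2
    logged = [(o.time, o.leaf_temp) for o in obs if o.leaf_temp is not None]
    if logged:
        lt, lv = map(np.asarray, zip(*logged))
        t_leaf_mid = np.interp(t_mid, lt, lv)
    else:
        t_leaf_mid = np.interp(t_mid, t, t_air) + leaf_air_offset
    t_air_mid = np.interp(t_mid, t, t_air)
    return np.array(
        [
            driving_force(
                VaporConditions(
                    t_leaf=float(tl), t_air=float(ta), a_apo=a_apo, a_air=a_air
                )
            )
            for tl, ta in zip(t_leaf_mid, t_air_mid)
        ]
    )


def conductance_series(
    intervals: Sequence[FluxInterval],
    driving,
    specimen: LeafSpecimen,
) -> list[ConductancePoint]:
    """Conductance g = J / driving force, with RWD at the midpoint weight.

    ``driving`` is a scalar or per-interval array of driving forces (g m-3),
    all strictly positive.
    """
    driving = np.broadcast_to(
        np.asarray(driving, dtype=float), (len(intervals),)
    )
    if np.any(driving <= 0):
        raise DryingError("driving force must be strictly positive")
    out = []
    for iv, d in zip(intervals, driving):
        rwd = relative_water_deficit(iv.w_mid, specimen)
        out.append(
            ConductancePoint(rwd=float(rwd), g=iv.j / float(d), j=iv.j,
                             t_mid=iv.t_mid)
        )
    return out


def _median3(y: np.ndarray) -> np.ndarray:
    """Centered 3-point running median; endpoints untouched."""
    out = y.copy()
    if len(y) >= 3:
        stacked = np.stack([y[:-2], y[1:-1], y[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def fit_drying_curve(
    points: Sequence[ConductancePoint],
    min_plateau: int = 3,
    median_filter: bool = False,
    flat_p: float = 0.05,
) -> GminResult:
    """Extract g_min and RWD_SC from a conductance-RWD drying curve.

    Fits a two-segment model: conductance declining linearly in RWD while
    stomata close, then a constant plateau (cuticle-only transpiration).
    The breakpoint is chosen by exhaustive grid search over all admissible
    splits of the ordered points, minimising the total residual sum of
    squares; ``rwd_sc`` is the abscissa where the declining line crosses the
    plateau level and ``g_min`` is the plateau mean.

    Raises :class:`PlateauOnlyError` when no declining phase is detectable
    (overall slope not significantly negative) and
    :class:`InsufficientPlateauError` when fewer than ``min_plateau`` points
    remain after the steepest admissible breakpoint.
    """
    from scipy import stats

    n = len(points)
    if n < 2 + min_plateau + 1:
        raise DryingError(
            f"need at least {3 + min_plateau} points (2 decline + "
            f"{min_plateau} plateau + 1), got {n}"
        )
    rwd = np.array([p.rwd for p in points], dtype=float)
    g = np.array([p.g for p in points], dtype=float)
    if np.any(np.diff(rwd) < -1e-9):
        raise DryingError("RWD must be non-decreasing along the series")
    if median_filter:
        g = _median3(g)

    # a drying curve must decline overall: slope of g on RWD significantly < 0
    sl = stats.linregress(rwd, g)
    if not (sl.slope < 0 and sl.pvalue < flat_p):
        raise PlateauOnlyError(
            "no declining phase detected (conductance statistically flat "
            f"in RWD: slope={sl.slope:.3g}, p={sl.pvalue:.3g})"
        )

    best = None
    for k in range(2, n - min_plateau + 1):  # decline = points[:k]
        x, y = rwd[:k], g[:k]
        sxx = np.sum((x - x.mean()) ** 2)
        if sxx == 0:
            continue
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        icpt = y.mean() - slope * x.mean()
        plateau = g[k:].mean()
        rss = (
            np.sum((y - (icpt + slope * x)) ** 2)
            + np.sum((g[k:] - plateau) ** 2)
        )
        if best is None or rss < best[0] - 1e-18:
            best = (rss, k, slope, icpt, plateau)
    if best is None:
        raise DryingError("no admissible breakpoint (degenerate RWD values)")
    rss, k, slope, icpt, plateau = best
    if slope >= 0:
        raise PlateauOnlyError(
            "declining segment has non-negative slope; no stomatal decline"
        )
    if n - k < min_plateau:
        raise InsufficientPlateauError(
            f"plateau has {n - k} points, need >= {min_plateau}"
        )
    # the "plateau" must actually be flat: a segment that keeps declining
    # both significantly and substantially (>20 % of its level over its RWD
    # span) means desiccation never reached the cuticle-only phase
    pl = stats.linregress(rwd[k:], g[k:])
    if len(set(rwd[k:])) >= 3 and pl.slope < 0 and pl.pvalue < flat_p:
        drop = abs(pl.slope) * (rwd[-1] - rwd[k]) / max(abs(g[k:].mean()), 1e-300)
        if drop > 0.2:
            raise InsufficientPlateauError(
                "tail segment still declining (relative drop "
                f"{drop:.2f} over its RWD span): no plateau reached"
            )
    rwd_sc = (plateau - icpt) / slope
    return GminResult(
        g_min=float(plateau),
        rwd_sc=float(rwd_sc),
        plateau_points=int(n - k),
        decline_slope=float(slope),
        fit_rss=float(rss),
    )
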