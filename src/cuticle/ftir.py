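"""Wax melting analysis from temperature-resolved ATR-FTIR spectra.

In long-chain alkyl crystals the CH2 asymmetric stretching band near
2916-2924 cm-1 shifts to higher wavenumbers as the chains disorder on
melting.  Tracking the band maximum over a temperature ladder therefore
yields a melting curve: low- and high-temperature plateaus connected by a
sigmoidal rise.  Waxes are multicomponent mixtures, so the transition is a
range, not a point; the melting midpoint is defined as the temperature at
which 50 % of the total frequency shift is reached, with onset and
completion at the 5 % and 95 % crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_WINDOW",
    "SpectrumFrame",
    "MeltingCurve",
    "FtirError",
    "band_maximum",
    "melting_analysis",
    "logistic_midpoint",
]

# CH2 asymmetric stretch search window (cm-1); the band sits near
# 2916-2924 cm-1 in alkyl crystals and shifts upward on melting.
DEFAULT_WINDOW = (2910.0, 2930.0)


class FtirError(ValueError):
    pass


@dataclass(frozen=True)
class SpectrumFrame:
    """One IR spectrum at one temperature: absorbance on a wavenumber grid."""

    temperature: float        # degC
    wavenumbers: np.ndarray   # cm-1, strictly monotone
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if nu.shape != ab.shape or nu.ndim != 1:
            raise FtirError("wavenumbers and absorbance must be equal-length 1-D")
        d = np.diff(nu)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise FtirError("wavenumber grid must be strictly monotone")
        if not np.all(np.isfinite(ab)):
            raise FtirError("non-finite absorbance")
        object.__setattr__(self, "wavenumbers", nu)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class MeltingCurve:
    points: tuple              # of (temperature degC, nu_max cm-1)
    onset: float | None        # degC, 5 % of total shift
    midpoint: float | None     # degC, 50 % of total shift
    completion: float | None   # degC, 95 % of total shift
    total_shift: float         # cm-1, high-T plateau minus low-T plateau
    transition: bool = True    # False when total shift below the floor
    midpoint_logistic: float | None = None  # degC, sigmoid-fit alternative
    #: set when the interpolation and logistic-fit midpoints differ by >1 degC
    method_discrepancy: bool = False


def band_maximum(frame: SpectrumFrame, window=DEFAULT_WINDOW) -> float:
    """Wavenumber (cm-1) of the absorbance maximum within ``window``.

    The grid argmax is refined sub-grid by a parabolic fit in
    log-absorbance over the upper half of the band (all contiguous points
    with absorbance >= half the peak) — exact for a Gaussian band profile
    and falling back to the minimal 3-point parabola on narrow peaks.  A
    flat window (tied maximum across it) has no unique band position and
    raises.
    """
    lo, hi = min(window), max(window)
    nu = frame.wavenumbers
    mask = (nu >= lo) & (nu <= hi)
    if mask.sum() < 3:
        raise FtirError(
            f"window [{lo}, {hi}] cm-1 covers {int(mask.sum())} grid points, "
            "need >= 3"
        )
    nu_w = nu[mask]
    ab_w = frame.absorbance[mask]
    if np.ptp(ab_w) == 0:
        raise FtirError("flat spectrum in window: no unique band maximum")
    order = np.argsort(nu_w)
    nu_w, ab_w = nu_w[order], ab_w[order]
    i = int(np.argmax(ab_w))
    if i in (0, len(ab_w) - 1):
        return float(nu_w[i])  # maximum at window edge; no parabola
    # contiguous run around the argmax with positive absorbance >= half max
    half = ab_w[i] / 2.0
    a = i
    while a > 0 and ab_w[a - 1] >= half and ab_w[a - 1] > 0:
        a -= 1
    b = i
    while b < len(ab_w) - 1 and ab_w[b + 1] >= half and ab_w[b + 1] > 0:
        b += 1
    a = min(a, i - 1)  # always include the immediate neighbours
    b = max(b, i + 1)
    x = nu_w[a:b + 1]
    y = ab_w[a:b + 1]
    if len(x) < 3 or np.any(y <= 0):
        x = nu_w[i - 1:i + 2]
        y = ab_w[i - 1:i + 2]
        if np.any(y <= 0):
            return float(nu_w[i])
    coef = np.polynomial.polynomial.polyfit(x - nu_w[i], np.log(y), 2)
    if coef[2] >= 0:  # not concave: no refined vertex
        return float(nu_w[i])
    vertex = -coef[1] / (2.0 * coef[2])
    step = float(np.mean(np.diff(nu_w)))
    return float(nu_w[i] + np.clip(vertex, -step, step))


def _smooth(y: np.ndarray) -> np.ndarray:
    """Centered 3-point median then 3-point mean; endpoints untouched.

    Identity on strictly monotone (noise-free) series up to the linear
    averaging, which preserves linear trends and sigmoid crossings on a
    uniform grid; on noisy series it suppresses single-frame outliers and
    roughly halves the frame-to-frame jitter.
    """
    if len(y) < 3:
        return y
    med = y.copy()
    med[1:-1] = np.median(np.stack([y[:-2], y[1:-1], y[2:]]), axis=0)
    out = med.copy()
    out[1:-1] = (med[:-2] + med[1:-1] + med[2:]) / 3.0
    return out


def logistic_midpoint(temps: np.ndarray, nu_max: np.ndarray) -> float | None:
    """Midpoint from a four-parameter logistic fit of nu_max(T).

    Alternative to the interpolation convention; returns None when the fit
    fails to converge or the fitted midpoint falls outside the temperature
    range.
    """
    from scipy.optimize import curve_fit

    temps = np.asarray(temps, dtype=float)
    nu_max = np.asarray(nu_max, dtype=float)

    def model(t, lo, span, m, w):
        return lo + span / (1.0 + np.exp(-(t - m) / w))

    p0 = (float(nu_max.min()), float(np.ptp(nu_max)),
          float(temps[np.argmin(np.abs(nu_max - nu_max.mean()))]), 3.0)
    try:
        popt, _ = curve_fit(model, temps, nu_max, p0=p0, maxfev=5000)
    except RuntimeError:
        return None
    m = float(popt[2])
    if not temps.min() <= m <= temps.max() or popt[3] <= 0 or popt[1] <= 0:
        return None
    return m


def _crossing(t: np.ndarray, s: np.ndarray, level: float) -> float | None:
    """First upward crossing of ``level`` by linear interpolation."""
    for i in range(1, len(s)):
        if s[i - 1] < level <= s[i]:
            if s[i] == s[i - 1]:
                return float(t[i])
            f = (level - s[i - 1]) / (s[i] - s[i - 1])
            return float(t[i - 1] + f * (t[i] - t[i - 1]))
    if len(s) and s[0] >= level:
        return float(t[0])
    return None


def melting_analysis(
    frames: Sequence[SpectrumFrame],
    window=DEFAULT_WINDOW,
    plateau_frames: int = 3,
    min_shift: float = 1.0,
    median_smooth: bool = True,
) -> MeltingCurve:
    """Melting curve from a temperature ladder of spectra.

    The band maximum is located per frame; the solid and molten plateau
    positions are the means over the first and last ``plateau_frames``
    frames.  The normalised shift s(T) = (nu(T) - nu_low)/(nu_high - nu_low)
    is interpolated linearly between frames; onset, midpoint and completion
    are its 0.05 / 0.50 / 0.95 crossings.  ``median_smooth`` denoises the
    located maxima (3-point median then 3-point mean) before the crossings
    are read off; it leaves linear trends and, on a uniform grid, sigmoid
    crossings in place.  A total shift below ``min_shift`` (cm-1) is
    reported as "no transition" rather than an error.  The sigmoid-fit
    alternative midpoint is reported alongside, with ``method_discrepancy``
    set when the two conventions differ by more than 1 degC.
    """
    if len(frames) < 2 * plateau_frames:
        raise FtirError(
            f"need >= {2 * plateau_frames} frames, got {len(frames)}"
        )
    temps = np.array([f.temperature for f in frames], dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise FtirError("frame temperatures must be strictly increasing")
    nu_raw = np.array([band_maximum(f, window) for f in frames])
    nu_max = _smooth(nu_raw) if median_smooth else nu_raw
    nu_low = nu_max[:plateau_frames].mean()
    nu_high = nu_max[-plateau_frames:].mean()
    shift = nu_high - nu_low
    pts = tuple(zip(temps.tolist(), nu_raw.tolist()))
    if shift < min_shift:
        return MeltingCurve(
            points=pts, onset=None, midpoint=None, completion=None,
            total_shift=float(shift), transition=False,
        )
    s = (nu_max - nu_low) / shift
    onset = _crossing(temps, s, 0.05)
    mid = _crossing(temps, s, 0.50)
    comp = _crossing(temps, s, 0.95)
    mid_fit = logistic_midpoint(temps, nu_raw)
    disagree = bool(
        mid is not None and mid_fit is not None and abs(mid - mid_fit) > 1.0
    )
    return MeltingCurve(
        points=pts, onset=onset, midpoint=mid, completion=comp,
        total_shift=float(shift), transition=True,
        midpoint_logistic=mid_fit, method_discrepancy=disagree,
    )
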