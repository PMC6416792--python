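"""Cuticular wax and cutin composition statistics.

Gas-chromatographic wax profiles arrive as surface coverages (µg cm-2) per
identified compound.  This module aggregates them by compound class,
converts to a mole-based carbon chain-length distribution, and computes the
weighted median chain length (MCL) — the 50 % weighted percentile of that
distribution — both as the discrete median chain length satisfying the
two half-weight inequalities

    sum_{i<k} w_i <= 1/2   and   sum_{i>k} w_i <= 1/2

and as a fractional value from linear interpolation of the cumulative
mole-fraction curve at 0.5.  A <C40 / >=C40 partition separates the
shorter-chain aliphatics from the very-long-chain alkyl esters, whose
chain length is counted as the summed carbons of the acid and alcohol
moieties.  Cutin depolymerisates are summarised by aliphatic/aromatic mass
percentages and the C16:C18 acid ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "COMPOUND_CLASSES",
    "WaxComponent",
    "ChainLengthDistribution",
    "MCLResult",
    "CutinMonomer",
    "WaxError",
    "homolog_molar_mass",
    "class_coverage",
    "mole_fractions",
    "mcl",
    "split_chain_fractions",
    "cutin_summary",
]

COMPOUND_CLASSES = (
    "n-alkane",
    "n-alkene",
    "n-aldehyde",
    "alkanoic acid",
    "primary alcohol",
    "secondary alcohol",
    "alkyl ester",
    "cyclic/other",
)

_M_C, _M_H, _M_O = 12.011, 1.008, 15.999

# (extra H, extra O) beyond the CnH2n backbone, per homologous series
_HOMOLOG_ADDENDA = {
    "n-alkane": (2, 0),          # CnH2n+2
    "n-alkene": (0, 0),          # CnH2n
    "n-aldehyde": (0, 1),        # CnH2nO
    "alkanoic acid": (0, 2),     # CnH2nO2
    "primary alcohol": (2, 1),   # CnH2n+2O
    "secondary alcohol": (2, 1),
    "alkyl ester": (0, 2),       # acid + alcohol - H2O = CnH2nO2
}


class WaxError(ValueError):
    pass


def homolog_molar_mass(compound_class: str, chain_length: int) -> float:
    """Molar mass (g mol-1) of an unbranched homolog from its class and
    total carbon number (alkyl esters: acid + alcohol carbons)."""
    try:
        extra_h, n_o = _HOMOLOG_ADDENDA[compound_class]
    except KeyError:
        raise WaxError(
            f"no homolog formula for class {compound_class!r}; "
            "provide molar_mass explicitly"
        ) from None
    n = int(chain_length)
    return n * _M_C + (2 * n + extra_h) * _M_H + n_o * _M_O


@dataclass(frozen=True)
class WaxComponent:
    """One GC-quantified wax constituent.

    ``chain_length`` is the total carbon count (for alkyl esters the summed
    acid + alcohol carbons).  ``molar_mass`` defaults to the standard
    homolog formula for the class; cyclic/other components have no homolog
    formula and need it given explicitly when moles are required.
    """

    name: str
    compound_class: str
    chain_length: int
    coverage: float  # µg cm-2
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise WaxError(
                f"unknown compound class {self.compound_class!r}; "
                f"expected one of {COMPOUND_CLASSES}"
            )
        if self.coverage < 0:
            raise WaxError(f"negative coverage for {self.name!r}")
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise WaxError(f"non-positive molar mass for {self.name!r}")
        if (
            self.compound_class != "cyclic/other"
            and self.chain_length < 16
        ):
            raise WaxError(
                f"{self.name!r}: chain length {self.chain_length} too short "
                "for a VLC aliphatic (>= 16 expected)"
            )

    def resolved_molar_mass(self) -> float:
        if self.molar_mass is not None:
            return self.molar_mass
        return homolog_molar_mass(self.compound_class, self.chain_length)


@dataclass(frozen=True)
class ChainLengthDistribution:
    """Mole fraction per carbon number; fractions sum to 1."""

    entries: tuple  # of (chain_length, weight), ordered by chain length

    def __post_init__(self) -> None:
        entries = tuple(sorted((int(n), float(w)) for n, w in dict(self.entries).items())
                        ) if isinstance(self.entries, Mapping) else tuple(
            sorted((int(n), float(w)) for n, w in self.entries))
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise WaxError("empty chain-length distribution")
        w = np.array([w for _, w in entries])
        if np.any(w < 0):
            raise WaxError("negative weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise WaxError(f"weights sum to {w.sum()}, expected 1")

    def lengths(self) -> np.ndarray:
        return np.array([n for n, _ in self.entries])

    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries])


@dataclass(frozen=True)
class MCLResult:
    """Weighted median carbon chain length, in both conventions."""

    eq_median: int                  # discrete weighted median
    interpolated_percentile: float  # cumulative curve crossed at 0.5
    tie_flag: bool                  # more than one chain length qualifies


@dataclass(frozen=True)
class CutinMonomer:
    name: str
    monomer_class: str          # 'aliphatic' | 'aromatic'
    coverage: float             # µg cm-2
    acid_chain_length: int | None = None

    def __post_init__(self) -> None:
        if self.monomer_class not in ("aliphatic", "aromatic"):
            raise WaxError(f"cutin class must be aliphatic/aromatic, "
                           f"got {self.monomer_class!r}")
        if self.coverage < 0:
            raise WaxError(f"negative coverage for {self.name!r}")


def class_coverage(components: Sequence[WaxComponent]) -> dict:
    """Coverage (µg cm-2) summed per compound class, plus ``'total'``.

    Classes with no components are absent from the map.
    """
    if not components:
        raise WaxError("empty component list")
    out: dict = {}
    for c in components:
        out[c.compound_class] = out.get(c.compound_class, 0.0) + c.coverage
    out["total"] = float(sum(c.coverage for c in components))
    return out


def mole_fractions(
    components: Sequence[WaxComponent], vlc_only: bool = True
) -> ChainLengthDistribution:
    """Mole-based chain-length distribution of a wax profile.

    Moles = coverage / molar mass, summed by carbon number and normalised.
    ``vlc_only`` drops cyclic/other components (the VLC aliphatic fraction
    used for MCL statistics); zero-coverage components are dropped.
    """
    moles: dict = {}
    for c in components:
        if vlc_only and c.compound_class == "cyclic/other":
            continue
        if c.coverage == 0:
            continue
        m = c.resolved_molar_mass()  # raises WaxError naming the component
        moles[c.chain_length] = moles.get(c.chain_length, 0.0) + c.coverage / m
    if not moles:
        raise WaxError("no components left after filtering")
    total = sum(moles.values())
    return ChainLengthDistribution(
        tuple((n, w / total) for n, w in sorted(moles.items()))
    )


def mcl(dist: ChainLengthDistribution) -> MCLResult:
    """Weighted median carbon chain length of a mole-fraction distribution.

    The discrete median is the smallest chain length N_k with at most half
    of the weight strictly below it and at most half strictly above it;
    ``tie_flag`` marks exact-half splits where more than one N_k qualifies.
    The interpolated percentile places the cumulative weight at each chain
    length and reads the 0.5 crossing off the piecewise-linear cumulative
    curve, giving the fractional MCL convention.
    """
    lengths = dist.lengths()
    w = dist.weights()
    cum = np.cumsum(w)
    below = cum - w          # sum over i < k
    above = 1.0 - cum        # sum over i > k
    ok = (below <= 0.5 + 1e-12) & (above <= 0.5 + 1e-12)
    idx = np.flatnonzero(ok)
    if idx.size == 0:  # unreachable for a valid distribution
        raise WaxError("no chain length satisfies the median inequalities")
    k = int(idx[0])
    # interpolated 50 % percentile of the cumulative curve
    j = int(np.searchsorted(cum, 0.5))
    if j == 0:
        interp = float(lengths[0])
    else:
        x0, x1 = lengths[j - 1], lengths[j]
        y0, y1 = cum[j - 1], cum[j]
        interp = float(x0 + (0.5 - y0) / (y1 - y0) * (x1 - x0)) \
            if y1 > y0 else float(x1)
    res = MCLResult(
        eq_median=int(lengths[k]),
        interpolated_percentile=interp,
        tie_flag=bool(idx.size > 1),
    )
    # post-hoc guard: the discrete median must satisfy both inequalities
    assert below[k] <= 0.5 + 1e-12 and above[k] <= 0.5 + 1e-12
    return res


def split_chain_fractions(
    dist: ChainLengthDistribution, cutoff: int = 40
) -> dict:
    """Partition the distribution at ``cutoff`` carbons.

    Returns mole percentages below / at-or-above the cutoff and the MCL of
    each renormalised sub-distribution (``None`` for an empty side).  The
    default cutoff separates shorter-chain aliphatics from the very-long-
    chain alkyl esters.
    """
    lengths, w = dist.lengths(), dist.weights()
    lo = lengths < cutoff
    p_lo = float(w[lo].sum()) * 100.0
    p_hi = float(w[~lo].sum()) * 100.0

    def _sub(mask) -> MCLResult | None:
        tot = w[mask].sum()
        if tot <= 0:
            return None
        sub = ChainLengthDistribution(
            tuple((int(n), float(x / tot)) for n, x in
                  zip(lengths[mask], w[mask]))
        )
        return mcl(sub)

    return {
        "below": p_lo,
        "at_or_above": p_hi,
        "mcl_below": _sub(lo),
        "mcl_at_or_above": _sub(~lo),
    }


def cutin_summary(monomers: Sequence[CutinMonomer]) -> dict:
    """Mass-based cutin summary: total coverage, aliphatic/aromatic
    percentages and the C16:C18 acid ratio.

    The ratio is coverage(C16 acids) / coverage(C18 acids); with no C18 it
    is ``inf`` (flagged), with neither chain length present it is ``None``.
    """
    if not monomers:
        raise WaxError("empty monomer list")
    total = sum(m.coverage for m in monomers)
    if total <= 0:
        raise WaxError("zero total cutin coverage")
    ali = sum(m.coverage for m in monomers if m.monomer_class == "aliphatic")
    aro = total - ali
    c16 = sum(m.coverage for m in monomers if m.acid_chain_length == 16)
    c18 = sum(m.coverage for m in monomers if m.acid_chain_length == 18)
    if c16 == 0 and c18 == 0:
        ratio = None
        degenerate = True
    elif c18 == 0:
        ratio = float("inf")
        degenerate = True
    else:
        ratio = c16 / c18
        degenerate = c16 == 0
    return {
        "total": float(total),
        "aliphatic_pct": 100.0 * ali / total,
        "aromatic_pct": 100.0 * aro / total,
        "c16_c18_ratio": ratio,
        "ratio_degenerate": degenerate,
    }
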