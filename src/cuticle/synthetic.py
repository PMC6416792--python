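"""Seeded generators for all three measurement kinds, with known truth.

The generators emulate the statistical structure of a detached-leaf study
of two desert species — a water-spender (colocynthis-like: thin leaf, high
g_min, temperature-sensitive barrier, alcohol-dominated unimodal wax) and a
water-saver (dactylifera-like: heavy leaflet, low g_min, flat thermal
response, ester-rich bimodal wax) — so the full analysis pipeline can be
exercised and validated closed-loop without any external data.

Every generator is a pure function of its config (seed included): the same
config reproduces the same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .drying import DryingObservation, LeafSpecimen
from .ftir import SpectrumFrame
from .psychro import GAS_CONSTANT, KELVIN_OFFSET, VaporConditions, driving_force
from .thermal import TemperatureSeries
from .waxes import WaxComponent

__all__ = [
    "DryingSimConfig",
    "MeltSimConfig",
    "TemperatureStudyConfig",
    "simulate_drying",
    "simulate_temperature_study",
    "simulate_ftir",
    "simulate_wax_profile",
]


def _default_specimen() -> LeafSpecimen:
    # broad-leaved water-spender morphology: thin lamina, high water content
    return LeafSpecimen(
        species="colocynthis-like",
        saturated_weight=0.82,
        dry_weight=0.14,
        projected_area_total=0.0045,
    )


@dataclass(frozen=True)
class DryingSimConfig:
    """Ground truth and protocol for one simulated drying run.

    Conductance declines from ``g_stomatal0 + true_g_min`` to the plateau
    ``true_g_min`` as stomata close over RWD in [0, true_rwd_sc]:

        g(RWD) = true_g_min + g_stomatal0 * max(0, 1 - RWD/true_rwd_sc)**closure_shape

    Weight loss integrates dW/dt = -g * D * A by explicit Euler at ``step``
    with D the driving force at leaf temperature (air + offset).  The
    defaults mirror a 25 degC run of the water-spender morphology weighed
    every 30 min for 12 h on a 0.1 mg balance.
    """

    seed: int = 0
    specimen: LeafSpecimen = field(default_factory=_default_specimen)
    true_g_min: float = 6.9e-5       # m s-1
    g_stomatal0: float = 5.0e-4      # m s-1, stomatal conductance at RWD=0
    true_rwd_sc: float = 0.14
    closure_shape: float = 1.0       # 1 = linear closure (piecewise-linear g)
    t_air: float = 25.0              # degC
    leaf_air_offset: float = 0.0     # degC
    step: float = 1800.0             # s between weighings
    duration: float = 43200.0        # s
    balance_noise_sd: float = 0.0    # g

    def __post_init__(self) -> None:
        if not self.true_g_min < self.g_stomatal0:
            raise ValueError("true_g_min must be < g_stomatal0")
        if not 0 < self.true_rwd_sc < 1:
            raise ValueError("true_rwd_sc must be in (0, 1)")


def simulate_drying(cfg: DryingSimConfig):
    """Simulate one drying run.

    Returns ``(specimen, observations, info)`` where ``info`` carries the
    ground truth and a ``reached_plateau`` flag (False when the duration was
    too short to desiccate past the stomatal-closure breakpoint).
    """
    rng = np.random.default_rng(cfg.seed)
    sp = cfg.specimen
    t_leaf = cfg.t_air + cfg.leaf_air_offset
    d = driving_force(VaporConditions(t_leaf=t_leaf, t_air=cfg.t_air))
    n_steps = int(round(cfg.duration / cfg.step))
    # fine Euler substeps keep the discretisation error well below 1 %
    sub = 20
    dt = cfg.step / sub
    w = sp.saturated_weight
    cap = sp.water_capacity
    times = [0.0]
    weights = [w]
    for i in range(n_steps):
        for _ in range(sub):
            rwd = 1.0 - (w - sp.dry_weight) / cap
            open_frac = max(0.0, 1.0 - rwd / cfg.true_rwd_sc)
            g = cfg.true_g_min + cfg.g_stomatal0 * open_frac**cfg.closure_shape
            w = max(sp.dry_weight, w - g * d * sp.projected_area_total * dt)
        times.append((i + 1) * cfg.step)
        weights.append(w)
    weights = np.array(weights)
    if cfg.balance_noise_sd > 0:
        weights = weights + rng.normal(0, cfg.balance_noise_sd, weights.shape)
    final_rwd = 1.0 - (weights[-1] - sp.dry_weight) / cap
    obs = [
        DryingObservation(
            time=float(t), fresh_weight=float(fw),
            air_temp=cfg.t_air, leaf_temp=t_leaf,
        )
        for t, fw in zip(times, weights)
    ]
    info = {
        "true_g_min": cfg.true_g_min,
        "true_rwd_sc": cfg.true_rwd_sc,
        "driving_force": d,
        "reached_plateau": bool(final_rwd > cfg.true_rwd_sc),
    }
    return sp, obs, info


#: Leaf-air temperature offset schedules (degC) per species template:
#: the water-spender cools increasingly above 30 degC (down to -4 degC at
#: 50 degC air temperature); the water-saver stays near -1 degC throughout.
def _leaf_air_offset(template: str, t_air: float) -> float:
    if template == "colocynthis-like":
        if t_air <= 30.0:
            return 0.0
        return -4.0 * (t_air - 30.0) / 20.0
    return -1.0


@dataclass(frozen=True)
class TemperatureStudyConfig:
    """Design of a g_min-vs-temperature study with a known Arrhenius law.

    ``law='single'`` draws every temperature from one Arrhenius line of
    activation energy ``ep_low`` (0 = flat).  ``law='biphasic'`` uses
    ``ep_low`` below ``break_temp`` and ``ep_high`` above, continuous at the
    break.  Replicates are lognormal around the law with coefficient of
    variation ``cv`` — matching the relative scatter of replicate leaves in
    this kind of gravimetric assay.  Six temperatures from 25 to 50 degC
    with n=8 replicates mirror the reference design.
    """

    seed: int = 0
    species: str = "synthetic"
    temperatures: tuple = (25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
    n_replicates: int = 8
    law: Literal["single", "biphasic"] = "biphasic"
    g_ref: float = 7.0e-5        # m s-1 at the low-T end of the law
    ep_low: float = 0.0          # kJ mol-1
    ep_high: float = 76.0        # kJ mol-1 (biphasic only)
    break_temp: float = 38.0     # degC (biphasic only)
    cv: float = 0.25

    def law_gmin(self, t_air) -> np.ndarray:
        """Noise-free g_min of the configured law at temperatures (degC)."""
        t = np.asarray(t_air, dtype=float)
        x = 1.0 / (t + KELVIN_OFFSET)
        x0 = 1.0 / (self.temperatures[0] + KELVIN_OFFSET)
        sl_lo = -self.ep_low * 1000.0 / GAS_CONSTANT
        lng = np.log(self.g_ref) + sl_lo * (x - x0)
        if self.law == "biphasic":
            xb = 1.0 / (self.break_temp + KELVIN_OFFSET)
            sl_hi = -self.ep_high * 1000.0 / GAS_CONSTANT
            lng_b = np.log(self.g_ref) + sl_lo * (xb - x0)
            hi = x < xb  # temperatures above the break
            lng = np.where(hi, lng_b + sl_hi * (x - xb), lng)
        out = np.exp(lng)
        return out if out.ndim else float(out)


def simulate_temperature_study(cfg: TemperatureStudyConfig):
    """Draw a replicate g_min study around the configured Arrhenius law.

    Returns ``(TemperatureSeries, truth)`` with the noise-free law values,
    activation energy and break temperature recorded in ``truth``.
    """
    if len(cfg.temperatures) < 2:
        raise ValueError("need >= 2 temperatures")
    rng = np.random.default_rng(cfg.seed)
    sigma = float(np.sqrt(np.log(1.0 + cfg.cv**2)))  # lognormal shape from CV
    entries = []
    for t in cfg.temperatures:
        mu = cfg.law_gmin(t)
        if cfg.cv > 0:
            # mean-preserving lognormal: E[g] = mu
            reps = mu * rng.lognormal(-0.5 * sigma**2, sigma, cfg.n_replicates)
        else:
            reps = np.full(cfg.n_replicates, mu)
        entries.append((float(t), tuple(float(g) for g in reps)))
    series = TemperatureSeries(species=cfg.species, entries=tuple(entries))
    truth = {
        "law": cfg.law,
        "ep_low": cfg.ep_low,
        "ep_high": cfg.ep_high if cfg.law == "biphasic" else None,
        "break_temp": cfg.break_temp if cfg.law == "biphasic" else None,
        "law_gmin": {float(t): float(cfg.law_gmin(t)) for t in cfg.temperatures},
    }
    return series, truth


def _default_ladder() -> tuple:
    """Reference heating protocol: 24 to 48 degC in 4 degC steps, then 48 to
    94 degC in 1 degC steps."""
    return tuple(np.concatenate([np.arange(24.0, 48.0, 4.0),
                                 np.arange(48.0, 95.0, 1.0)]).tolist())


@dataclass(frozen=True)
class MeltSimConfig:
    """Sigmoidal band-shift ground truth for a simulated melting series.

    Each frame holds one Gaussian CH2 band whose centre moves from
    ``nu_low`` to ``nu_high`` along a logistic in temperature centred at
    ``midpoint`` with scale ``width``.  Two noise channels: Gaussian
    absorbance noise (``noise_sd``, band peak = 1) and Gaussian jitter of
    the band centre itself (``center_jitter_sd``, cm-1), mimicking
    frame-to-frame drift of the located maximum.
    """

    seed: int = 0
    nu_low: float = 2918.0    # cm-1, crystalline band position
    nu_high: float = 2924.0   # cm-1, molten band position
    midpoint: float = 73.0    # degC
    width: float = 3.0        # degC, logistic scale
    temp_ladder: tuple = field(default_factory=_default_ladder)
    band_fwhm: float = 12.0   # cm-1
    noise_sd: float = 0.0     # absorbance units (band peak = 1)
    center_jitter_sd: float = 0.0  # cm-1, noise on the band position
    grid: tuple = (2880.0, 2960.0, 2.0)  # cm-1: lo, hi, step

    def center(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = 1.0 / (1.0 + np.exp(-(t - self.midpoint) / self.width))
        c = self.nu_low + (self.nu_high - self.nu_low) * s
        return c if c.ndim else float(c)


def simulate_ftir(cfg: MeltSimConfig) -> list[SpectrumFrame]:
    """Simulate a temperature ladder of single-band IR spectra."""
    if cfg.nu_high <= cfg.nu_low:
        raise ValueError("nu_high must exceed nu_low")
    rng = np.random.default_rng(cfg.seed)
    lo, hi, step = cfg.grid
    nu = np.arange(lo, hi + step / 2, step)
    sigma = cfg.band_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    frames = []
    for t in cfg.temp_ladder:
        c = cfg.center(t)
        if cfg.center_jitter_sd > 0:
            c = c + rng.normal(0, cfg.center_jitter_sd)
        ab = np.exp(-0.5 * ((nu - c) / sigma) ** 2)
        if cfg.noise_sd > 0:
            ab = ab + rng.normal(0, cfg.noise_sd, ab.shape)
        frames.append(
            SpectrumFrame(temperature=float(t), wavenumbers=nu.copy(),
                          absorbance=ab)
        )
    return frames


# Wax profile templates: (name, class, chain length, mean coverage µg cm-2).
# The colocynthis-like template is a sparse, primary-alcohol-dominated
# profile (C28-C32 modes, ~4 µg cm-2 total, <2 mol% >= C40); the
# dactylifera-like template is ester-rich and bimodal (~29 µg cm-2 total,
# ~30 mol% >= C40 alkyl esters around C48-C58).
_TEMPLATES: dict = {
    "colocynthis-like": (
        ("hexacosan-1-ol", "primary alcohol", 26, 0.20),
        ("octacosan-1-ol", "primary alcohol", 28, 0.55),
        ("triacontan-1-ol", "primary alcohol", 30, 1.10),
        ("dotriacontan-1-ol", "primary alcohol", 32, 0.55),
        ("octacosanal", "n-aldehyde", 28, 0.25),
        ("triacontanal", "n-aldehyde", 30, 0.30),
        ("nonacosane", "n-alkane", 29, 0.25),
        ("hentriacontane", "n-alkane", 31, 0.30),
        ("octacosanoic acid", "alkanoic acid", 28, 0.20),
        ("triacontanoic acid", "alkanoic acid", 30, 0.25),
        ("alkyl ester C44", "alkyl ester", 44, 0.05),
        ("triterpenoid mix", "cyclic/other", 30, 0.04),
    ),
    "dactylifera-like": (
        ("octacosan-1-ol", "primary alcohol", 28, 1.00),
        ("triacontan-1-ol", "primary alcohol", 30, 1.50),
        ("nonacosane", "n-alkane", 29, 1.20),
        ("hentriacontane", "n-alkane", 31, 1.50),
        ("triacontanal", "n-aldehyde", 30, 1.20),
        ("dotriacontanal", "n-aldehyde", 32, 1.50),
        ("triacontanoic acid", "alkanoic acid", 30, 2.00),
        ("dotriacontanoic acid", "alkanoic acid", 32, 4.40),
        ("tetratriacontanoic acid", "alkanoic acid", 34, 1.60),
        ("alkyl ester C48", "alkyl ester", 48, 2.90),
        ("alkyl ester C50", "alkyl ester", 50, 2.10),
        ("alkyl ester C52", "alkyl ester", 52, 2.00),
        ("alkyl ester C54", "alkyl ester", 54, 1.80),
        ("alkyl ester C56", "alkyl ester", 56, 1.80),
        ("alkyl ester C58", "alkyl ester", 58, 1.80),
        ("sterol mix", "cyclic/other", 29, 1.10),
    ),
}


def simulate_wax_profile(
    species_template: Literal["colocynthis-like", "dactylifera-like"],
    seed: int = 0,
    cv: float = 0.10,
) -> list[WaxComponent]:
    """Draw a wax profile around a species template.

    Coverages are lognormal around the template means with coefficient of
    variation ``cv`` (GC replicate scatter).  Cyclic components carry an
    explicit nominal molar mass since they have no homolog formula.
    """
    try:
        template = _TEMPLATES[species_template]
    except KeyError:
        raise ValueError(
            f"unknown template {species_template!r}; expected one of "
            f"{tuple(_TEMPLATES)}"
        ) from None
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + cv**2))) if cv > 0 else 0.0
    out = []
    for name, cls, n, mean_cov in template:
        cov = mean_cov * rng.lognormal(-0.5 * sigma**2, sigma) if cv > 0 \
            else mean_cov
        mm = 426.7 if cls == "cyclic/other" else None  # nominal triterpenoid
        out.append(
            WaxComponent(name=name, compound_class=cls, chain_length=n,
                         coverage=float(cov), molar_mass=mm)
        )
    return out
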