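"""Published reference data for the two desert study species.

Summary statistics from a gravimetric study of the water-spender
*Citrullus colocynthis* and the water-saver *Phoenix dactylifera*:
per-temperature means and standard deviations of minimum leaf conductance
and of the relative water deficit at stomatal closure (n >= 8 leaves per
cell), and mean leaf morphology (n >= 61).  These serve as worked-example
inputs for the Arrhenius and morphology routines; raw drying curves were
not published, so replicate-level analyses run on synthetic data instead.
"""

from __future__ import annotations

import numpy as np

from .drying import LeafSpecimen

__all__ = [
    "GMIN_TEMPERATURES",
    "GMIN_MEAN",
    "GMIN_SD",
    "RWD_SC_MEAN",
    "MORPHOLOGY",
    "reference_specimen",
    "gmin_means",
]

#: Air temperatures (degC) of the g_min study.
GMIN_TEMPERATURES = (25.0, 30.0, 35.0, 40.0, 45.0, 50.0)

#: Mean minimum conductance (m s-1) per species and air temperature.
GMIN_MEAN = {
    "C. colocynthis": (6.94e-5, 7.83e-5, 7.74e-5, 8.79e-5, 13.70e-5, 21.98e-5),
    "P. dactylifera": (1.11e-5, 0.92e-5, 1.00e-5, 1.19e-5, 1.37e-5, 1.30e-5),
}

#: Standard deviation of g_min (m s-1), same layout.
GMIN_SD = {
    "C. colocynthis": (2.00e-5, 1.23e-5, 1.46e-5, 2.41e-5, 5.33e-5, 5.19e-5),
    "P. dactylifera": (0.24e-5, 0.16e-5, 0.12e-5, 0.47e-5, 0.32e-5, 0.26e-5),
}

#: Mean relative water deficit at maximum stomatal closure.
RWD_SC_MEAN = {
    "C. colocynthis": (0.14, 0.15, 0.16, 0.20, 0.30, 0.60),
    "P. dactylifera": (0.014, 0.010, 0.014, 0.011, 0.015, 0.016),
}

#: Mean leaf morphology: saturated/dry weight (g) and total projected
#: area (m2, adaxial + abaxial).
MORPHOLOGY = {
    "C. colocynthis": {"saturated_weight": 0.82, "dry_weight": 0.14,
                       "projected_area_total": 0.0045},
    "P. dactylifera": {"saturated_weight": 1.27, "dry_weight": 0.59,
                       "projected_area_total": 0.0074},
}


def reference_specimen(species: str) -> LeafSpecimen:
    """Mean-morphology specimen for one of the two reference species."""
    m = MORPHOLOGY[species]
    return LeafSpecimen(species=species, **m)


def gmin_means(species: str) -> np.ndarray:
    """(temperature degC, mean g_min m s-1) array for one species."""
    return np.column_stack([GMIN_TEMPERATURES, GMIN_MEAN[species]])
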