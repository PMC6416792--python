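import numpy as np
import pytest

import cuticle as c
from cuticle.data import GMIN_TEMPERATURES, GMIN_MEAN


@pytest.fixture
def specimen():
    """Water-spender-like leaf morphology."""
    return c.LeafSpecimen(
        species="test",
        saturated_weight=1.0,
        dry_weight=0.2,
        projected_area_total=0.005,
    )


def series_from_means(species: str) -> c.TemperatureSeries:
    """Reference per-temperature mean g_min as single-replicate entries."""
    return c.TemperatureSeries(
        species=species,
        entries=tuple(
            (t, (g,)) for t, g in zip(GMIN_TEMPERATURES, GMIN_MEAN[species])
        ),
    )


@pytest.fixture
def colocynthis_series():
    return series_from_means("C. colocynthis")


@pytest.fixture
def dactylifera_series():
    return series_from_means("P. dactylifera")


def brute_force_weighted_median(lengths, weights):
    """Independent oracle: enumerate every chain length and test the two
    half-weight inequalities directly; return the smallest qualifying one
    and whether more than one qualifies."""
    order = np.argsort(lengths)
    lengths = np.asarray(lengths)[order]
    weights = np.asarray(weights)[order]
    qualifying = []
    for k in range(len(lengths)):
        below = weights[:k].sum()
        above = weights[k + 1:].sum()
        if below <= 0.5 + 1e-12 and above <= 0.5 + 1e-12:
            qualifying.append(int(lengths[k]))
    return qualifying[0], len(qualifying) > 1
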