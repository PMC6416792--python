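import numpy as np
import pytest

import cuticle as c
from cuticle.drying import (
    ConductancePoint,
    DryingError,
    FluxInterval,
    InsufficientPlateauError,
    PlateauOnlyError,
    interval_driving_forces,
)


def obs(times, weights, air=25.0):
    return [
        c.DryingObservation(time=t, fresh_weight=w, air_temp=air)
        for t, w in zip(times, weights)
    ]


class TestRelativeWaterDeficit:
    def test_endpoints_and_midpoint(self, specimen):
        assert c.relative_water_deficit(1.0, specimen) == 0.0
        assert c.relative_water_deficit(0.2, specimen) == 1.0
        assert c.relative_water_deficit(0.6, specimen) == 0.5

    def test_balance_noise_clipped_with_warning(self, specimen):
        with pytest.warns(UserWarning, match="clipped"):
            assert c.relative_water_deficit(1.01, specimen) == 0.0

    def test_gross_violation_rejected(self, specimen):
        with pytest.raises(DryingError):
            c.relative_water_deficit(1.1, specimen)

    def test_degenerate_specimen_rejected(self):
        with pytest.raises(DryingError):
            c.LeafSpecimen(species="x", saturated_weight=0.5,
                           dry_weight=0.5, projected_area_total=0.01)


class TestMorphology:
    def test_water_spender_water_content(self):
        sp = c.LeafSpecimen("cc", saturated_weight=0.82, dry_weight=0.14,
                            projected_area_total=0.0045)
        assert c.morphology_traits(sp)["lwc"] == pytest.approx(0.829, abs=0.001)

    def test_water_saver_water_content_and_lma(self):
        sp = c.LeafSpecimen("pd", saturated_weight=1.27, dry_weight=0.59,
                            projected_area_total=0.0074)
        traits = c.morphology_traits(sp)
        assert traits["lwc"] == pytest.approx(0.535, abs=0.001)
        # LMA on one-sided area: 0.59 g / 0.0037 m2
        assert traits["lma"] == pytest.approx(159.46, abs=0.1)


class TestTranspirationSeries:
    def test_hand_computed_flux(self, specimen):
        out = c.transpiration_series(
            obs([0, 1800], [1.0, 0.982]), specimen
        )
        assert out[0].j == pytest.approx(0.018 / (1800 * 0.005))
        assert out[0].t_mid == 900

    def test_constant_weight_gives_zero_flux(self, specimen):
        out = c.transpiration_series(obs([0, 600, 1200], [0.9, 0.9, 0.9]),
                                     specimen)
        assert [iv.j for iv in out] == [0.0, 0.0]

    def test_three_point_series_matches_finite_differences(self, specimen):
        t = [0.0, 1000.0, 3000.0]
        w = [1.0, 0.95, 0.89]
        out = c.transpiration_series(obs(t, w), specimen)
        expected = [
            (w[i] - w[i + 1]) / ((t[i + 1] - t[i]) * 0.005) for i in range(2)
        ]
        assert [iv.j for iv in out] == pytest.approx(expected)

    def test_weight_gain_flagged_not_dropped(self, specimen):
        out = c.transpiration_series(obs([0, 600], [0.9, 0.901]), specimen)
        assert out[0].flagged and out[0].j < 0

    def test_duplicate_timestamps_rejected(self, specimen):
        with pytest.raises(DryingError, match="duplicate"):
            c.transpiration_series(obs([0, 600, 600], [1, 0.9, 0.8]), specimen)


class TestConductanceSeries:
    def test_flux_over_driving_force(self, specimen):
        iv = [FluxInterval(t_mid=0, j=1.3e-3, w_mid=0.9)]
        pts = c.conductance_series(iv, 18.7, specimen)
        assert pts[0].g == pytest.approx(6.95e-5, rel=0.001)

    def test_high_temperature_driving_force(self, specimen):
        iv = [FluxInterval(t_mid=0, j=1.0e-3, w_mid=0.9)]
        pts = c.conductance_series(iv, 77.0, specimen)
        assert pts[0].g == pytest.approx(1.3e-5, rel=0.01)

    def test_zero_flux_zero_conductance(self, specimen):
        pts = c.conductance_series(
            [FluxInterval(t_mid=0, j=0.0, w_mid=0.9)], 20.0, specimen
        )
        assert pts[0].g == 0.0

    def test_zero_driving_force_rejected(self, specimen):
        with pytest.raises(DryingError):
            c.conductance_series(
                [FluxInterval(t_mid=0, j=1e-3, w_mid=0.9)], 0.0, specimen
            )

    def test_leaf_temperature_interpolated_between_loggings(self):
        o = [
            c.DryingObservation(time=0, fresh_weight=1.0, air_temp=25,
                                leaf_temp=24.0),
            c.DryingObservation(time=1800, fresh_weight=0.99, air_temp=25),
            c.DryingObservation(time=3600, fresh_weight=0.98, air_temp=25,
                                leaf_temp=22.0),
        ]
        d = interval_driving_forces(o)
        # midpoints at 900 s and 2700 s -> leaf temps 23.5 and 22.5 degC
        assert d[0] == pytest.approx(c.saturation_vapor_concentration(23.5))
        assert d[1] == pytest.approx(c.saturation_vapor_concentration(22.5))


def piecewise_points(rwds, g_min=1e-5, rwd_sc=0.15, g0=5e-4, rwd0=0.02):
    """Noise-free decline from g0 at rwd0 to g_min at rwd_sc, then plateau."""
    slope = (g_min - g0) / (rwd_sc - rwd0)
    g = np.where(rwds < rwd_sc, g0 + slope * (rwds - rwd0), g_min)
    return [
        ConductancePoint(rwd=float(r), g=float(v), j=0.0, t_mid=float(i))
        for i, (r, v) in enumerate(zip(rwds, g))
    ]


class TestFitDryingCurve:
    def test_noiseless_exact_recovery(self):
        rwds = np.concatenate([np.linspace(0.02, 0.15, 6),
                               np.linspace(0.18, 0.5, 8)])
        res = c.fit_drying_curve(piecewise_points(rwds))
        assert res.g_min == pytest.approx(1e-5, abs=1e-15)
        assert res.rwd_sc == pytest.approx(0.15, abs=1e-10)
        assert res.plateau_points >= 3
        assert res.fit_rss == pytest.approx(0.0, abs=1e-20)

    def test_invariant_to_extra_decline_points(self):
        base = None
        for n_decline in (4, 6, 10):
            rwds = np.concatenate([np.linspace(0.02, 0.15, n_decline),
                                   np.linspace(0.18, 0.5, 8)])
            res = c.fit_drying_curve(piecewise_points(rwds))
            if base is None:
                base = res
            assert res.g_min == pytest.approx(base.g_min, rel=1e-9)
            assert res.rwd_sc == pytest.approx(base.rwd_sc, abs=1e-9)

    def test_monotone_decline_without_plateau_rejected(self):
        rwds = np.linspace(0.02, 0.5, 12)
        g = 5e-4 - 9e-4 * (rwds - 0.02)  # pure decline, no flat part
        pts = [ConductancePoint(rwd=float(r), g=float(v), j=0.0, t_mid=i)
               for i, (r, v) in enumerate(zip(rwds, g))]
        with pytest.raises(InsufficientPlateauError):
            c.fit_drying_curve(pts)

    def test_flat_series_rejected_as_plateau_only(self):
        rwds = np.linspace(0.1, 0.5, 10)
        pts = [ConductancePoint(rwd=float(r), g=1e-5, j=0.0, t_mid=i)
               for i, r in enumerate(rwds)]
        with pytest.raises(PlateauOnlyError):
            c.fit_drying_curve(pts)

    def test_too_few_points_rejected(self):
        rwds = np.linspace(0.02, 0.3, 5)
        with pytest.raises(DryingError):
            c.fit_drying_curve(piecewise_points(rwds))

    def test_decreasing_rwd_rejected(self):
        pts = piecewise_points(np.linspace(0.02, 0.5, 10))
        pts[3], pts[4] = pts[4], pts[3]
        bad = [ConductancePoint(rwd=pts[i].rwd, g=pts[i].g, j=0.0, t_mid=i)
               for i in range(len(pts))]
        with pytest.raises(DryingError):
            c.fit_drying_curve(bad)


def test_pipeline_identity_zero_noise():
    """Generator -> flux -> conductance -> fit recovers the configured
    ground truth within discretization error (<1 %)."""
    cfg = c.DryingSimConfig(seed=0, balance_noise_sd=0.0)
    sp, o, info = c.simulate_drying(cfg)
    intervals = c.transpiration_series(o, sp)
    driving = interval_driving_forces(o)
    pts = c.conductance_series(intervals, driving, sp)
    res = c.fit_drying_curve(pts)
    assert res.g_min == pytest.approx(info["true_g_min"], rel=0.01)
    assert res.rwd_sc == pytest.approx(info["true_rwd_sc"], rel=0.01)
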