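import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cuticle as c
from cuticle.waxes import CutinMonomer, WaxError, homolog_molar_mass
from conftest import brute_force_weighted_median


def comp(name="x", cls="n-alkane", n=29, cov=1.0, mm=None):
    return c.WaxComponent(name=name, compound_class=cls, chain_length=n,
                          coverage=cov, molar_mass=mm)


class TestClassCoverage:
    def test_sums_per_class_and_total(self):
        out = c.class_coverage([comp(cov=1.0), comp(name="y", cov=2.0)])
        assert out == {"n-alkane": 3.0, "total": 3.0}

    def test_mixed_table_matches_hand_sum(self):
        comps = [
            comp("a", "n-alkane", 29, 0.3),
            comp("b", "n-alkane", 31, 0.7),
            comp("c", "primary alcohol", 30, 1.1),
            comp("d", "alkyl ester", 48, 2.2, mm=705.3),
            comp("e", "cyclic/other", 30, 0.1, mm=426.7),
        ]
        out = c.class_coverage(comps)
        assert out["n-alkane"] == pytest.approx(1.0)
        assert out["primary alcohol"] == pytest.approx(1.1)
        assert out["total"] == pytest.approx(4.4)
        assert "n-aldehyde" not in out

    def test_negative_coverage_rejected(self):
        with pytest.raises(WaxError):
            comp(cov=-0.1)


class TestMolarMasses:
    @pytest.mark.parametrize(
        "cls, n, expected",
        [
            ("n-alkane", 29, 408.8),          # C29H60
            ("primary alcohol", 30, 438.8),   # C30H62O
            ("alkanoic acid", 32, 480.8),     # C32H64O2
            ("alkyl ester", 48, 705.3),       # C48H96O2
        ],
    )
    def test_homolog_formulas(self, cls, n, expected):
        assert homolog_molar_mass(cls, n) == pytest.approx(expected, abs=0.2)

    def test_cyclic_requires_explicit_mass(self):
        cy = comp(cls="cyclic/other", n=30)
        with pytest.raises(WaxError, match="x"):
            c.mole_fractions([cy], vlc_only=False)


class TestMoleFractions:
    def test_single_component(self):
        dist = c.mole_fractions([comp(n=30)])
        assert dist.entries == ((30, 1.0),)

    def test_equal_masses_weighted_by_inverse_molar_mass(self):
        a = comp("alc", "primary alcohol", 28, 1.0)
        b = comp("acid", "alkanoic acid", 32, 1.0)
        dist = c.mole_fractions([a, b])
        ma = homolog_molar_mass("primary alcohol", 28)
        mb = homolog_molar_mass("alkanoic acid", 32)
        expected_28 = (1 / ma) / (1 / ma + 1 / mb)
        assert dict(dist.entries)[28] == pytest.approx(expected_28)

    def test_zero_coverage_dropped_and_vlc_filter(self):
        comps = [comp(n=29), comp("z", n=31, cov=0.0),
                 comp("cy", "cyclic/other", 30, 1.0, mm=400.0)]
        dist = c.mole_fractions(comps, vlc_only=True)
        assert dist.lengths().tolist() == [29]
        dist_all = c.mole_fractions(comps, vlc_only=False)
        assert dist_all.lengths().tolist() == [29, 30]

    def test_invariant_under_uniform_rescaling(self):
        comps = [comp("a", n=28, cov=0.4), comp("b", n=32, cov=1.8)]
        scaled = [comp("a", n=28, cov=4.0), comp("b", n=32, cov=18.0)]
        w1 = c.mole_fractions(comps).weights()
        w2 = c.mole_fractions(scaled).weights()
        assert w1 == pytest.approx(w2, rel=1e-12)


class TestMCL:
    def test_point_mass(self):
        res = c.mcl(c.ChainLengthDistribution(((30, 1.0),)))
        assert res.eq_median == 30
        assert res.interpolated_percentile == 30.0

    def test_symmetric_three_component(self):
        res = c.mcl(c.ChainLengthDistribution(((28, 0.25), (30, 0.5),
                                               (32, 0.25))))
        assert res.eq_median == 30
        assert not res.tie_flag

    def test_exact_half_split_ties(self):
        res = c.mcl(c.ChainLengthDistribution(((28, 0.5), (32, 0.5))))
        assert res.eq_median == 28  # smallest qualifying chain length
        assert res.tie_flag

    def test_brute_force_equivalence_1000_random_distributions(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = rng.integers(1, 12)
            lengths = rng.choice(np.arange(20, 63), size=k, replace=False)
            w = rng.dirichlet(np.ones(k))
            dist = c.ChainLengthDistribution(
                tuple((int(n), float(x)) for n, x in zip(lengths, w))
            )
            res = c.mcl(dist)
            expect, tie = brute_force_weighted_median(lengths, w)
            assert res.eq_median == expect
            assert res.tie_flag == tie

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_median_inequalities_always_satisfied(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 10))
        lengths = rng.choice(np.arange(16, 70), size=k, replace=False)
        w = rng.dirichlet(np.ones(k) * 0.5)
        dist = c.ChainLengthDistribution(
            tuple((int(n), float(x)) for n, x in zip(lengths, w))
        )
        res = c.mcl(dist)
        d = dict(dist.entries)
        below = sum(v for n, v in d.items() if n < res.eq_median)
        above = sum(v for n, v in d.items() if n > res.eq_median)
        assert below <= 0.5 + 1e-9 and above <= 0.5 + 1e-9
        assert dist.lengths().min() <= res.interpolated_percentile \
            <= dist.lengths().max()

    def test_interpolated_near_discrete_for_unimodal(self):
        # unimodal, 2-carbon steps: the two conventions stay within 2 C
        dist = c.ChainLengthDistribution(
            ((26, 0.1), (28, 0.2), (30, 0.35), (32, 0.2), (34, 0.15))
        )
        res = c.mcl(dist)
        assert abs(res.interpolated_percentile - res.eq_median) <= 2.0

    def test_empty_distribution_rejected(self):
        with pytest.raises(WaxError):
            c.ChainLengthDistribution(())


class TestSplitChainFractions:
    def test_simple_partition(self):
        dist = c.ChainLengthDistribution(((38, 0.6), (48, 0.4)))
        out = c.split_chain_fractions(dist, cutoff=40)
        assert out["below"] == pytest.approx(60.0)
        assert out["at_or_above"] == pytest.approx(40.0)
        assert out["below"] + out["at_or_above"] == pytest.approx(100.0)

    def test_empty_partition_gives_none(self):
        dist = c.ChainLengthDistribution(((30, 0.7), (34, 0.3)))
        out = c.split_chain_fractions(dist)
        assert out["at_or_above"] == 0.0
        assert out["mcl_at_or_above"] is None
        assert out["mcl_below"].eq_median == 30

    def test_bimodal_submedians_straddle_the_modes(self):
        # short mode near C31, ester mode near C51
        dist = c.ChainLengthDistribution(
            ((29, 0.2), (31, 0.3), (33, 0.2), (49, 0.1), (51, 0.12),
             (53, 0.08))
        )
        out = c.split_chain_fractions(dist)
        assert out["mcl_below"].eq_median == 31
        assert out["mcl_at_or_above"].eq_median == 51


class TestCutinSummary:
    def mono(self, name, cls, n, cov):
        return CutinMonomer(name=name, monomer_class=cls,
                            acid_chain_length=n, coverage=cov)

    def test_c16_dominated_ratio(self):
        out = c.cutin_summary([
            self.mono("dhp", "aliphatic", 16, 60.0),
            self.mono("heo", "aliphatic", 18, 10.0),
        ])
        assert out["c16_c18_ratio"] == pytest.approx(6.0)
        assert not out["ratio_degenerate"]

    def test_class_percentages(self):
        out = c.cutin_summary([
            self.mono("ali", "aliphatic", 16, 88.0),
            self.mono("cou", "aromatic", None, 12.0),
        ])
        assert out["aliphatic_pct"] == pytest.approx(88.0)
        assert out["aromatic_pct"] == pytest.approx(12.0)

    def test_only_c18_present_is_degenerate(self):
        out = c.cutin_summary([self.mono("heo", "aliphatic", 18, 10.0)])
        assert out["c16_c18_ratio"] == 0.0
        assert out["ratio_degenerate"]

    def test_no_c16_c18_gives_none(self):
        out = c.cutin_summary([self.mono("x", "aliphatic", 22, 1.0)])
        assert out["c16_c18_ratio"] is None
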