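"""The analytical equilibrium theory against oracles and limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kaeff.network import (
    build_pair_network,
    ka_eff_from_state,
    solve_equilibrium,
)
from kaeff.parameters import Geometry, PairParameters
from kaeff.theory import (
    FitError,
    critical_lipid_concentration,
    enhancement_at,
    fit_ka2d_from_enhancement,
    ka_eff,
    ka_pm_weighted_average,
    lambda_fraction,
    m_eq,
    m_eq_coop,
    m_eq_zero,
    membrane_fraction_of_complexes,
)
from kaeff.units import ka_molar_to_um3, molar_to_per_um3, per_um3_to_molar

uM = molar_to_per_um3(1e-6)
perM = ka_molar_to_um3(1.0)


def brute_force_free_lipid(m_tot, p_tot, ka):
    """Bisection on the single-site mass balance (independent oracle)."""

    def residual(m):
        return m + ka * m * p_tot / (1.0 + ka * m) - m_tot

    lo, hi = 0.0, m_tot
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestMEqZero:
    def test_no_binding_returns_total(self):
        assert m_eq_zero(3.0, 1.0, 0.0) == 3.0

    def test_golden_ratio_case(self):
        # equal totals at Ka * [tot] = 1 leaves (sqrt(5)-1)/2 of the lipid free
        m = m_eq_zero(1.0 * uM, 1.0 * uM, 1e6 * perM)
        assert per_um3_to_molar(m) * 1e6 == pytest.approx(0.6180, rel=1e-4)

    def test_excess_lipid_case(self):
        m = m_eq_zero(100.0 * uM, 1.0 * uM, 1e6 * perM)
        assert per_um3_to_molar(m) * 1e6 == pytest.approx(99.01, rel=1e-4)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.floats(min_value=-2, max_value=3),
        st.floats(min_value=-2, max_value=2),
        st.floats(min_value=3, max_value=8),
    )
    def test_matches_fixed_point_oracle(self, log_m, log_p, log_ka):
        m_tot, p_tot, ka = 10**log_m * uM, 10**log_p * uM, 10**log_ka * perM
        expected = brute_force_free_lipid(m_tot, p_tot, ka)
        assert m_eq_zero(m_tot, p_tot, ka) == pytest.approx(expected, rel=1e-9)


class TestWeightedAverage:
    def test_equal_constants_for_any_weights(self):
        assert ka_pm_weighted_average(2.0, 2.0, 5.0, 1.0) == 2.0

    def test_symmetric_weights(self):
        assert ka_pm_weighted_average(1e6, 0.0, 1.0, 1.0) == 5e5

    def test_asymmetric_example(self):
        assert ka_pm_weighted_average(1e6, 1e4, 3.0, 1.0) == pytest.approx(
            7.525e5
        )

    def test_zero_weights_fall_back_to_mean(self):
        assert ka_pm_weighted_average(4.0, 2.0, 0.0, 0.0) == 3.0


class TestLambda:
    def test_limits(self):
        assert lambda_fraction(1.0, 1.0, 0.0) == 0.0
        assert lambda_fraction(1.0, 1.0, math.inf) == 1.0
        assert lambda_fraction(0.0, 1.0, 1.0) == 0.0

    def test_golden_ratio_case(self):
        lam = lambda_fraction(1.0 * uM, 1.0 * uM, 1e6 * perM)
        assert lam == pytest.approx(0.3820, rel=1e-4)
        # consistency: complexed fraction = 1 - free fraction of the
        # equivalent single-site balance at equal totals
        assert lam == pytest.approx(
            1.0 - m_eq_zero(1.0 * uM, 1.0 * uM, 1e6 * perM) / (1.0 * uM),
            rel=1e-9,
        )

    def test_huge_ka_is_overflow_safe(self):
        lam = lambda_fraction(1.0 * uM, 2.0 * uM, 1e15 * perM)
        assert 0.0 <= lam <= 1.0
        assert lam == pytest.approx(1.0, abs=1e-6)


class TestMEqCoop:
    def test_no_lipid_binding_returns_total(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 0.0, 0.0, 1e-6, 1e-6, unit_geometry, m_tot_molar=1e-5
        )
        assert m_eq_coop(p) == pytest.approx(p.m_tot_volume)

    def test_excess_lipid_limit(self, excess_lipid_params):
        m = m_eq_coop(excess_lipid_params)
        assert m == pytest.approx(excess_lipid_params.m_tot_volume, rel=0.05)

    @pytest.mark.parametrize("p1_uM, p2_uM", [(2.0, 2.0), (3.0, 1.0)])
    def test_matches_ode_oracle_at_huge_ka_pp(self, p1_uM, p2_uM):
        # the Ka_PP -> infinity limit, realized in the network at 1e14 /M
        p = PairParameters.from_molar(
            1e14, 1e4, 1e5, p1_uM * 1e-6, p2_uM * 1e-6,
            Geometry(V=0.76, A=1.0), sigma_nm=1.0, m_tot_per_um2=1e3,
        )
        st_eq = solve_equilibrium(build_pair_network(p))
        assert m_eq_coop(p) == pytest.approx(st_eq["M"], rel=1e-4)


class TestMEqInterpolation:
    def test_ka_pp_zero_reduces_to_single_site(self, unit_geometry):
        p = PairParameters.from_molar(
            0.0, 1e6, 1e6, 1e-6, 1e-6, unit_geometry, m_tot_per_um2=2.5e4
        )
        comp = m_eq(p)
        assert comp.lam == 0.0
        assert comp.m_eq == comp.m_eq_zero

    def test_excess_lipid_limit(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 1e6, 1e6, 1e-8, 1e-8, unit_geometry, m_tot_molar=1e-5
        )
        comp = m_eq(p)
        assert abs(comp.m_eq - p.m_tot_volume) / p.m_tot_volume < 0.01

    def test_lipid_limited_strong_ka_pp(self, lipid_limited_params):
        p = lipid_limited_params.with_(ka_pp=ka_molar_to_um3(1e9))
        st_eq = solve_equilibrium(build_pair_network(p))
        assert m_eq(p).m_eq == pytest.approx(st_eq["M"], rel=0.05)

    def test_interpolate_is_bounded_by_its_components(self, lipid_limited_params):
        comp = m_eq(lipid_limited_params)
        lo = min(comp.m_eq_zero, comp.m_eq_coop)
        hi = max(comp.m_eq_zero, comp.m_eq_coop)
        assert lo <= comp.m_eq <= hi
        assert 0.0 <= comp.lam <= 1.0

    def test_self_consistent_mode_converges(self, lipid_limited_params):
        comp = m_eq(lipid_limited_params, self_consistent=True)
        assert comp.converged


class TestKaEff:
    def test_no_lipid_binding_means_no_enhancement(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 0.0, 0.0, 1e-6, 1e-6, unit_geometry, m_tot_per_um2=2.5e4
        )
        assert ka_eff(p).enhancement == pytest.approx(1.0)

    def test_one_binder_means_no_enhancement(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 1e6, 0.0, 1e-6, 1e-6, unit_geometry, m_tot_per_um2=2.5e4
        )
        assert ka_eff(p).enhancement == pytest.approx(1.0)

    def test_unit_stickiness_arithmetic(self):
        # stickiness 1 for both partners at gamma 100: (100+2+1)/4
        p = PairParameters(
            ka_pp=1.0, ka_p1m=1.0, ka_p2m=1.0, p1_tot=1.0, p2_tot=1.0,
            geometry=Geometry(V=200.0, A=1.0), sigma_pp=1e-3, m_tot=1.0,
        )
        assert p.gamma == pytest.approx(1e5)
        assert enhancement_at(p.with_(geometry=Geometry(V=0.2, A=1.0)), 1.0) \
            == pytest.approx(25.75)

    def test_sticky_limit_reaches_gamma(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 1e9, 1e9, 1e-9, 1e-9, unit_geometry, m_tot_per_um2=2.5e4
        )
        res = ka_eff(p)
        assert res.enhancement == pytest.approx(res.gamma, rel=1e-3)

    def test_complexation_bounds(self, excess_lipid_params):
        res = ka_eff(excess_lipid_params)
        assert 0.0 <= res.pct_complexation <= 100.0
        assert res.membrane_fraction is not None
        assert 0.0 <= res.membrane_fraction <= 1.0
        assert res.ka_eff >= excess_lipid_params.ka_pp
        assert res.enhancement < res.gamma

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=4, max_value=9),
        st.floats(min_value=3, max_value=7),
        st.floats(min_value=3, max_value=7),
        st.floats(min_value=-8, max_value=-5.5),
        st.floats(min_value=-0.5, max_value=1.0),
    )
    def test_enhancement_bounds_property(self, lkpp, lk1, lk2, lp, lva):
        # gamma > 1, both partners lipid-binding: 1 <= enhancement < gamma
        geom = Geometry(V=10**lva, A=1.0)
        p = PairParameters.from_molar(
            10**lkpp, 10**lk1, 10**lk2, 10**lp, 10**lp, geom, sigma_nm=1.0,
            m_tot_per_um2=2.5e4,
        )
        res = ka_eff(p)
        assert p.gamma > 1
        assert 1.0 - 1e-9 <= res.enhancement < p.gamma

    def test_reduction_requires_gamma_below_one(self):
        # V/A < 2 sigma: localization dilutes binding below the solution value
        geom = Geometry(V=0.001, A=1.0)  # V/A = 1 nm < 2 nm
        p = PairParameters.from_molar(
            1e6, 1e8, 1e8, 1e-6, 1e-6, geom, sigma_nm=1.0, m_tot_per_um2=2.5e4
        )
        assert p.gamma < 1.0
        assert ka_eff(p).enhancement < 1.0

    def test_enhancement_nonincreasing_in_protein_concentration(self, unit_geometry):
        enh = [
            ka_eff(
                PairParameters.from_molar(
                    1e6, 1e5, 1e5, c, c, unit_geometry, m_tot_per_um2=1e3
                )
            ).enhancement
            for c in (1e-8, 1e-7, 1e-6, 1e-5)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(enh, enh[1:]))

    def test_membrane_bound_protein_increases_with_ka_pp(self, lipid_limited_params):
        # cooperativity: a stronger protein-protein bond pulls more protein
        # onto the membrane at fixed lipid parameters
        def membrane_bound(ka_pp):
            p = lipid_limited_params.with_(ka_pp=ka_molar_to_um3(ka_pp))
            st_eq = solve_equilibrium(build_pair_network(p))
            return st_eq.species_total("P1", "membrane") + st_eq.species_total(
                "P2", "membrane"
            )

        vals = [membrane_bound(k) for k in (1e4, 1e6, 1e8)]
        assert vals[0] < vals[1] < vals[2]


class TestMembraneFraction:
    def test_no_lipid_binding_gives_null(self, unit_geometry):
        p = PairParameters.from_molar(
            0.0, 0.0, 0.0, 1e-6, 1e-6, unit_geometry, m_tot_per_um2=2.5e4
        )
        res = ka_eff(p)
        assert membrane_fraction_of_complexes(p, res) is None  # no complexes

    def test_sticky_limit_puts_all_complexes_on_membrane(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 1e9, 1e9, 1e-9, 1e-9, unit_geometry, m_tot_per_um2=2.5e4
        )
        res = ka_eff(p)
        assert membrane_fraction_of_complexes(p, res) == pytest.approx(1.0, abs=1e-4)

    def test_matches_ode_species_sums(self, excess_lipid_params):
        p = excess_lipid_params
        st_eq = solve_equilibrium(build_pair_network(p))
        mem = st_eq["MP1P2"] + st_eq["P1P2M"] + st_eq["MP1P2M"]
        tot = mem + st_eq["P1P2"]
        res = ka_eff(p)
        assert membrane_fraction_of_complexes(p, res) == pytest.approx(
            mem / tot, rel=1e-4
        )


class TestCriticalLipid:
    def test_epsilon_one_returns_zero(self, excess_lipid_params):
        assert critical_lipid_concentration(excess_lipid_params, 1.0) == 0.0

    def test_defining_property(self, excess_lipid_params):
        p = excess_lipid_params
        mc = critical_lipid_concentration(p, 0.01)
        enh = ka_eff(p.with_(m_tot=mc, m_tot_per_area=None)).enhancement
        assert 0.99 <= enh / p.gamma <= 0.99 + 1e-6

    def test_monotone_in_lipid_affinity(self, excess_lipid_params):
        weak = critical_lipid_concentration(
            excess_lipid_params.with_(
                ka_p1m=ka_molar_to_um3(1e5), ka_p2m=ka_molar_to_um3(1e5)
            )
        )
        strong = critical_lipid_concentration(
            excess_lipid_params.with_(
                ka_p1m=ka_molar_to_um3(1e7), ka_p2m=ka_molar_to_um3(1e7)
            )
        )
        assert strong < weak

    def test_unreachable_target_is_null(self):
        geom = Geometry(V=0.001, A=1.0)  # gamma < 1
        p = PairParameters.from_molar(
            1e6, 1e6, 1e6, 1e-6, 1e-6, geom, m_tot_per_um2=2.5e4
        )
        assert critical_lipid_concentration(p) is None


class TestFitSigma:
    def test_calmodulin_style_extraction(self):
        fit = fit_ka2d_from_enhancement(500.0, Geometry(V=6.7, A=1.0))
        assert fit.sigma * 1e3 == pytest.approx(6.7)

    def test_round_trip_through_the_theory(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 1e8, 1e8, 1e-8, 1e-8, unit_geometry, sigma_nm=2.0,
            m_tot_per_um2=2.5e4,
        )
        res = ka_eff(p)
        fit = fit_ka2d_from_enhancement(
            res.enhancement, p.geometry,
            stickiness=(res.stickiness_1, res.stickiness_2),
        )
        p_back = p.with_(sigma_pp=fit.sigma, sigma_p1m=None, sigma_p2m=None)
        assert ka_eff(p_back).enhancement == pytest.approx(
            res.enhancement, rel=1e-8
        )
        assert fit.sigma == pytest.approx(p.sigma_pp, rel=1e-6)

    def test_enhancement_of_one_is_rejected(self, unit_geometry):
        with pytest.raises(FitError):
            fit_ka2d_from_enhancement(
                1.0, unit_geometry, stickiness=(2.0, 2.0)
            )


class TestDistinctLipids:
    def test_two_pools_match_shared_pool_when_symmetric(self, unit_geometry):
        shared = PairParameters.from_molar(
            1e6, 1e6, 1e6, 1e-7, 1e-7, unit_geometry, m_tot_molar=1e-5
        )
        # each protein sees its own pool of the same size: with excess
        # lipids the enhancement agrees up to the (small) extra depletion
        # of the shared pool
        distinct = shared.with_(distinct_lipids=True)
        assert ka_eff(distinct).enhancement == pytest.approx(
            ka_eff(shared).enhancement, rel=1e-2
        )

    def test_emptying_one_pool_kills_enhancement(self, unit_geometry):
        p = PairParameters.from_molar(
            1e6, 1e6, 1e6, 1e-7, 1e-7, unit_geometry, m_tot_molar=1e-5
        ).with_(distinct_lipids=True, m2_tot=0.0)
        assert ka_eff(p).enhancement == pytest.approx(1.0, rel=1e-6)
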