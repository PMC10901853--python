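"""Vegetation kernel: NPP responses, turnover, steady-state biomass."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vegrange as vr
from vegrange.vegetation import (DEFAULT_PFTS, ConvergenceError,
                                 PhotosynthesisParams, npp_cell)


class TestInsolation:
    def test_normalised_at_present_day_equator(self):
        assert vr.insolation_factor(0.0, 0.0) == 1.0

    def test_faint_young_sun_five_percent(self):
        # luminosity 1/(1 + 0.4*541/4570) at the start of the Phanerozoic
        assert vr.insolation_factor(0.0, 541.0) == pytest.approx(0.955, abs=5e-4)

    def test_decreases_with_latitude(self):
        assert vr.insolation_factor(60.0, 0.0) < vr.insolation_factor(30.0, 0.0)


class TestLeafRespiration:
    @pytest.mark.parametrize("h,a,expected", [(12, 0.015, 0.03),
                                              (24, 0.07, 0.07),
                                              (12, 0.0, 0.0)])
    def test_values(self, h, a, expected):
        assert vr.leaf_respiration_rate(h, a) == pytest.approx(expected)

    def test_invalid_hours(self):
        with pytest.raises(ValueError):
            vr.leaf_respiration_rate(0.0, 0.015)


class TestTurnover:
    @pytest.mark.parametrize("o2,expected", [(0.35, 0.20),   # upper clamp
                                             (0.21, 0.1012),  # linear branch
                                             (0.10, 0.08)])   # lower clamp
    def test_values(self, o2, expected):
        assert vr.turnover_fraction(o2) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_and_bounded(self, o2a, o2b):
        ta, tb = vr.turnover_fraction(o2a), vr.turnover_fraction(o2b)
        assert 0.08 <= ta <= 0.2
        if o2a <= o2b:
            assert ta <= tb


class TestNppCell:
    TROP = DEFAULT_PFTS["tropical"]

    def test_no_runoff_means_no_npp(self):
        assert npp_cell(27.0, 0.0, 1.0, 1.0, 0.21, self.TROP) == 0.0

    def test_below_minus_ten_is_uninhabitable(self):
        assert npp_cell(-12.0, 500.0, 1.0, 1.0, 0.21, self.TROP) == 0.0

    def test_outside_pft_window_is_zero(self):
        assert npp_cell(60.0, 500.0, 1.0, 1.0, 0.21, self.TROP) == 0.0

    def test_ceiling_binds_in_optimal_cell(self):
        # optimal temperature, saturating water, full light, high CO2
        p = PhotosynthesisParams()
        assert npp_cell(27.0, 5000.0, 1.0, 16.0, 0.21, self.TROP, p) == p.npp_max

    def test_present_day_o2_is_neutral(self):
        import dataclasses

        p = PhotosynthesisParams()
        p_off = dataclasses.replace(p, o2_sensitivity=0.0)
        a = npp_cell(27.0, 100.0, 0.9, 1.0, 0.21, self.TROP, p)
        b = npp_cell(27.0, 100.0, 0.9, 1.0, 0.21, self.TROP, p_off)
        assert a == pytest.approx(b)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.0, 3000.0), st.floats(0.0, 3000.0),
           st.floats(0.1, 1.0), st.floats(0.1, 1.0))
    def test_monotone_in_runoff_and_insolation(self, r1, r2, l1, l2):
        n11 = npp_cell(27.0, r1, l1, 1.0, 0.21, self.TROP)
        n21 = npp_cell(27.0, r2, l1, 1.0, 0.21, self.TROP)
        n12 = npp_cell(27.0, r1, l2, 1.0, 0.21, self.TROP)
        if r1 <= r2:
            assert n11 <= n21
        if l1 <= l2:
            assert n11 <= n12


class TestNppGrid:
    def test_warm_wet_equator_is_tropical(self, dispersed_world, forcing):
        climate = vr.synth_climate(dispersed_world, forcing)
        npp, dom = vr.npp_grid(climate, forcing, 1.0, dispersed_world)
        eq = np.argmin(np.abs(dispersed_world.lat_centers))
        warm_wet = (climate.runoff[eq] > 100) & (climate.temperature[eq] >= 25.0)
        assert warm_wet.any()
        assert np.all(dom[eq][warm_wet] == 1)  # tropical code

    def test_temperate_wins_exact_tie_with_boreal(self):
        # at 20 degC both mid-latitude types sit on their optimal plateaus
        t, b = DEFAULT_PFTS["temperate"], DEFAULT_PFTS["boreal"]
        nt = npp_cell(20.0, 400.0, 0.8, 1.0, 0.21, t)
        nb = npp_cell(20.0, 400.0, 0.8, 1.0, 0.21, b)
        assert nt == nb
        g = vr.make_grid(4, 4)
        w = g.with_mask(np.ones(g.shape, bool))
        climate = vr.ClimateField(temperature=np.full(g.shape, 20.0),
                                  runoff=np.full(g.shape, 400.0),
                                  insolation_rel=np.full(g.shape, 0.8))
        _, dom = vr.npp_grid(climate, vr.ForcingState(), 1.0, w)
        assert np.all(dom == 2)  # temperate code, by tie priority

    def test_all_ocean_grid_is_barren(self, forcing):
        g = vr.make_grid(5, 6)
        climate = vr.synth_climate(g, forcing)
        npp, dom = vr.npp_grid(climate, forcing, 1.0, g)
        assert np.all(npp == 0) and np.all(dom == 0)

    def test_shape_mismatch_rejected(self, dispersed_world, forcing):
        g = vr.make_grid(5, 6)
        climate = vr.synth_climate(g, forcing)
        with pytest.raises(ValueError):
            vr.npp_grid(climate, forcing, 1.0, dispersed_world)


def _analytic_iterations(npp, tau, seed, tol):
    """Closed-form solution of the stop rule of the biomass recurrence.

    b_n = b* + (1-tau)^n (b0 - b*); convergence at the first n with
    |b* - b_{n-1}| <= tol * b_n in every habitable cell.
    """
    npp = npp[npp > 0]
    if npp.size == 0:
        return 0
    b_star = npp / tau
    for n in range(1, 5000):
        b_prev = b_star + (1 - tau) ** (n - 1) * (seed - b_star)
        b_n = b_star + (1 - tau) ** n * (seed - b_star)
        if np.all(np.abs(b_star - b_prev) <= tol * b_n):
            return n
    raise AssertionError("analytic bound not found")


class TestSteadyBiomass:
    def test_uniform_npp_matches_closed_form(self):
        npp = np.full((4, 5), 1000.0)
        state = vr.spin_to_steady_biomass(npp, 0.21)
        tau = vr.turnover_fraction(0.21)
        np.testing.assert_allclose(state.biomass, 1000.0 / tau, rtol=0.01)

    def test_barren_world_converges_immediately(self):
        state = vr.spin_to_steady_biomass(np.zeros((3, 3)), 0.21)
        assert np.all(state.biomass == 0)
        assert not state.habitable.any()
        assert state.iterations_to_converge == 0

    @pytest.mark.parametrize("rng_seed", [0, 1, 2])
    def test_randomized_grids_match_closed_form_and_bound(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        npp = rng.uniform(0.0, 3200.0, size=(10, 12))
        npp[rng.random(npp.shape) < 0.3] = 0.0
        state = vr.spin_to_steady_biomass(npp, 0.21)
        tau = vr.turnover_fraction(0.21)
        hab = npp > 0
        np.testing.assert_allclose(state.biomass[hab], npp[hab] / tau, rtol=0.01)
        assert np.all(state.biomass[~hab] == 0)
        expected = _analytic_iterations(npp, tau, vr.SEED_BIOMASS, 0.01)
        assert abs(state.iterations_to_converge - expected) <= 1

    def test_bit_reproducible(self):
        rng = np.random.default_rng(5)
        npp = rng.uniform(0, 2000, size=(6, 7))
        a = vr.spin_to_steady_biomass(npp, 0.25)
        b = vr.spin_to_steady_biomass(npp, 0.25)
        assert np.array_equal(a.biomass, b.biomass)
        assert a.iterations_to_converge == b.iterations_to_converge

    def test_non_convergence_raises_with_diagnostics(self):
        npp = np.full((2, 2), 500.0)
        with pytest.raises(ConvergenceError, match="iterations"):
            vr.spin_to_steady_biomass(npp, 0.21, max_iter=3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            vr.spin_to_steady_biomass(np.ones((2, 2)), 0.21, tol=0.0)
        with pytest.raises(ValueError):
            vr.spin_to_steady_biomass(np.ones((2, 2)), 0.21, seed_biomass=-1.0)


class TestDiagnostics:
    def test_habitable_area_half_on_equal_area_cells(self):
        g = vr.make_grid(2, 2)  # all four cells share the same area
        w = g.with_mask(np.ones(g.shape, bool))
        npp = np.array([[100.0, 0.0], [100.0, 0.0]])
        state = vr.spin_to_steady_biomass(npp, 0.21)
        frac, area = vr.habitable_area(state, w)
        assert frac == pytest.approx(0.5)
        assert area == pytest.approx(0.5 * w.land_area)

    def test_habitable_area_extremes(self):
        g = vr.make_grid(2, 2)
        w = g.with_mask(np.ones(g.shape, bool))
        empty = vr.spin_to_steady_biomass(np.zeros(g.shape), 0.21)
        assert vr.habitable_area(empty, w) == (0.0, 0.0)
        full = vr.spin_to_steady_biomass(np.full(g.shape, 100.0), 0.21)
        frac, area = vr.habitable_area(full, w)
        assert frac == 1.0 and area == pytest.approx(w.land_area)

    def test_habitable_area_requires_land(self):
        g = vr.make_grid(2, 2)
        state = vr.spin_to_steady_biomass(np.zeros(g.shape), 0.21)
        with pytest.raises(ValueError):
            vr.habitable_area(state, g)

    def test_relative_vegetation_is_linear(self):
        g = vr.make_grid(3, 4)
        w = g.with_mask(np.ones(g.shape, bool))
        state = vr.spin_to_steady_biomass(np.full(g.shape, 200.0), 0.21)
        base = vr.total_biomass(state, w)
        assert vr.relative_vegetation(state, w, base) == pytest.approx(1.0)
        state.biomass = 2 * state.biomass
        assert vr.relative_vegetation(state, w, base) == pytest.approx(2.0)
        state.biomass = np.zeros(g.shape)
        assert vr.relative_vegetation(state, w, base) == 0.0
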