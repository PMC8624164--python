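import math

import numpy as np
import pytest

from enceladus_niche.biomass_monod import (
    CONSTANTS,
    GrowthParameters,
    HydrogenBudget,
    cells_from_biomass,
    default_budget,
    default_growth_parameters,
    default_time_grid,
    hydrogen_supply_rate,
    linear_growth,
    monod_ode,
    scenario_concentration,
    specific_growth_rate,
)


class TestHydrogenBudget:
    def test_plume_lifetime_release(self):
        r = hydrogen_supply_rate(default_budget())
        assert r.plume_release_total == pytest.approx(2.28e19, rel=1e-12)

    def test_ocean_remaining_total(self):
        r = hydrogen_supply_rate(default_budget())
        assert r.ocean_remaining_total == pytest.approx(17.72e19, rel=1e-12)

    def test_supply_rate_direct_arithmetic(self):
        r = hydrogen_supply_rate(default_budget())
        expected = 17.72e19 / (4.56e9 * 1.70e22)
        assert r.St == pytest.approx(expected, rel=1e-12)
        assert r.St == pytest.approx(2.29e-12, rel=0.01)

    def test_overdrawn_budget_rejected(self):
        with pytest.raises(ValueError):
            HydrogenBudget(plume_release_rate_max=1e11)

    def test_constants_registry_has_units_and_provenance(self):
        for name, entry in CONSTANTS.items():
            assert entry["value"] > 0, name
            assert entry["units"], name
            assert entry["provenance"], name


class TestLinearGrowth:
    def test_initial_condition(self):
        p = default_growth_parameters()
        traj = linear_growth(p, St=2.3e-12, t_grid=np.array([0.0, 1.0]))
        assert traj.X[0] == p.X0
        assert traj.cells[0] == pytest.approx(1.0)  # 1 cell/cm^3

    def test_zero_yield_keeps_biomass_constant(self):
        p = GrowthParameters(Y=0.0)
        traj = linear_growth(p, St=2.3e-12, t_grid=np.linspace(0, 1e9, 5))
        np.testing.assert_allclose(traj.X, p.X0)

    def test_headline_magnitude(self):
        """Y*St*t at 3.5 Gyr is ~3.2e-3 g/cm^3, ~1.6e11 cells/cm^3."""
        p = default_growth_parameters()
        St = hydrogen_supply_rate(default_budget()).St
        traj = linear_growth(p, St, np.array([3.5e9]))
        assert traj.X[-1] == pytest.approx(0.4 * St * 3.5e9, rel=1e-9)
        assert traj.cells[-1] == pytest.approx(1.6e11, rel=0.05)

    def test_doubling_yield_doubles_gain(self):
        St, t = 2.3e-12, np.linspace(0, 3.5e9, 7)
        p1 = GrowthParameters(Y=0.4)
        p2 = GrowthParameters(Y=0.8)
        g1 = linear_growth(p1, St, t).X - p1.X0
        g2 = linear_growth(p2, St, t).X - p2.X0
        np.testing.assert_allclose(g2, 2.0 * g1)

    def test_biomass_non_decreasing(self):
        traj = linear_growth(default_growth_parameters(), 2.3e-12,
                             default_time_grid())
        assert np.all(np.diff(traj.X) >= 0)


class TestCellsFromBiomass:
    @pytest.mark.parametrize("X,expected", [
        (0.0, 0.0),
        (2e-14, 1.0),
        (3.23e-3, 1.615e11),
    ])
    def test_division(self, X, expected):
        assert cells_from_biomass(X, 2e-14) == pytest.approx(expected)

    def test_positive_cell_mass_required(self):
        with pytest.raises(ValueError):
            cells_from_biomass(1.0, 0.0)


class TestMonodODE:
    @pytest.fixture()
    def params(self):
        return GrowthParameters(Y=0.4, mu_max=0.5, Ks=1e-12, X0=2e-14)

    def test_mass_balance_without_supply(self, params):
        """X + Y*S is conserved when supply = 0."""
        S0 = 1e-10
        t = np.linspace(1.0, 60.0, 30)
        traj = monod_ode(params, S0=S0, supply=0.0, t_grid=t, rtol=1e-10)
        total = traj.X + params.Y * traj.S
        np.testing.assert_allclose(total, params.X0 + params.Y * S0, rtol=1e-6)

    def test_exponential_limit_at_saturation(self, params):
        """With S >> Ks growth is exponential at mu_max within 1%."""
        S0 = 1e-6  # Monod factor > 0.999999 throughout the short horizon
        t = np.linspace(0.1, 10.0, 20)
        traj = monod_ode(params, S0=S0, supply=0.0, t_grid=t, rtol=1e-10)
        factor = traj.S / (params.Ks + traj.S)
        assert factor.min() > 0.99
        expected = params.X0 * np.exp(params.mu_max * t)
        np.testing.assert_allclose(traj.X, expected, rtol=0.01)

    def test_half_saturation_initial_rate(self, params):
        """mu(Ks) * X0 is exactly mu_max * X0 / 2."""
        rate = specific_growth_rate(params, params.Ks) * params.X0
        assert rate == params.mu_max * params.X0 / 2.0

    def test_supply_replacing_consumption_matches_linear_growth(self):
        """Saturated substrate and consumption == supply: X tracks the
        linear solution X0 + Y*supply*t within 1%."""
        St, Y, X0 = 2.3e-12, 0.4, 2e-14
        # initial consumption (mu_max * X0 / Y) exactly equals the supply
        mu_max = Y * St / X0
        params = GrowthParameters(Y=Y, X0=X0, mu_max=mu_max, Ks=1e-12)
        S0 = 1e-8  # >> Ks, so the Monod factor stays >= 0.999 throughout
        t = np.linspace(0.001 / mu_max, 0.1 / mu_max, 20)
        traj = monod_ode(params, S0=S0, supply=St, t_grid=t, rtol=1e-10)
        factor = traj.S / (params.Ks + traj.S)
        assert factor.min() >= 0.999
        linear = linear_growth(params, St, t)
        np.testing.assert_allclose(traj.X, linear.X, rtol=0.01)

    def test_biomass_non_decreasing_with_supply(self, params):
        traj = monod_ode(params, S0=1e-11, supply=1e-12,
                         t_grid=np.linspace(1, 100, 40))
        assert np.all(np.diff(traj.X) >= -1e-25)

    def test_invalid_parameters_fatal(self):
        p = GrowthParameters(mu_max=0.0)
        with pytest.raises(ValueError):
            monod_ode(p, S0=1e-10, supply=0.0, t_grid=np.array([1.0, 2.0]))


class TestScenarios:
    def test_full_ocean_order_of_magnitude_11(self):
        res = scenario_concentration(
            default_growth_parameters(), default_budget(), "full_ocean", 3.5e9)
        assert res["order_of_magnitude"] == 11

    def test_hydrothermal_order_of_magnitude_10(self):
        res = scenario_concentration(
            default_growth_parameters(), default_budget(), "hydrothermal",
            3.5e9)
        assert res["order_of_magnitude"] == 10

    def test_short_horizon_returns_initial_concentration(self):
        res = scenario_concentration(
            default_growth_parameters(), default_budget(), "full_ocean", 1e-6)
        assert res["cells_per_cm3"] == pytest.approx(1.0, rel=1e-3)

    def test_unknown_scenario_fatal(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_concentration(
                default_growth_parameters(), default_budget(), "plume", 1e9)

    def test_hydrothermal_scales_supply_by_stripe_fraction(self):
        b = default_budget()
        full = scenario_concentration(
            default_growth_parameters(), b, "full_ocean", 3.5e9)
        hydro = scenario_concentration(
            default_growth_parameters(), b, "hydrothermal", 3.5e9)
        assert hydro["St_mol_per_cm3_yr"] == pytest.approx(
            full["St_mol_per_cm3_yr"] * b.stripe_area_fraction)
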