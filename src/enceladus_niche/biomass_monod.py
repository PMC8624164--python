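"""Hydrogen-budget and Monod growth model for methanogens in Enceladus' ocean.

The limiting substrate is molecular hydrogen produced by serpentinization
(aqueous oxidation of reduced core minerals).  Cassini plume measurements
bound the present-day escape of H2 through the plume at 1–5 x 10^9 mol/yr;
integrating the maximum rate over the age of the solar system (4.56 Gyr)
gives 2.28 x 10^19 mol vented, out of a theoretical serpentinization yield
of ~20 x 10^19 mol, leaving 17.72 x 10^19 mol available in the ocean.
Spread uniformly in time and over the 1.70 x 10^22 cm^3 ocean this is a
constant volumetric supply rate S_t of roughly 2.3 x 10^-12 mol H2 cm^-3
yr^-1.

Growth follows Monod kinetics,

    dX/dt = mu_max * S / (Ks + S) * X,
    dS/dt = supply - (1/Y) * mu_max * S / (Ks + S) * X,

with yield Y (g dry weight per mol H2).  When cells consume hydrogen as
fast as it is supplied, biomass accumulates linearly:

    dX/dt = -Y dS/dt  =>  X(t) = X0 + Y * S_t * t,

and cell concentration is X / m_cell with m_cell ~ 2 x 10^-14 g per cell.
Two spatial scenarios bracket the answer: hydrogen consumed throughout the
whole ocean, or only within the water column above the hydrothermally
active seafloor under the south-polar tiger stripes (9% of the seafloor
area), which scales the harvestable supply by that area fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

__all__ = [
    "HydrogenBudget",
    "GrowthParameters",
    "GrowthTrajectory",
    "SupplyRateResult",
    "CONSTANTS",
    "default_budget",
    "default_growth_parameters",
    "hydrogen_supply_rate",
    "specific_growth_rate",
    "linear_growth",
    "monod_ode",
    "scenario_concentration",
    "cells_from_biomass",
    "default_time_grid",
]

# Single registry of the physical constants used by the model, each with a
# provenance note pointing at the measurement or model it comes from.
CONSTANTS: dict[str, dict] = {
    "plume_release_rate_max": {
        "value": 5.0e9, "units": "mol H2 / yr",
        "provenance": "upper end of the 1-5e9 mol/yr H2 plume escape rate "
                      "measured by Cassini INMS during plume flythroughs",
    },
    "theoretical_total_H2": {
        "value": 20.0e19, "units": "mol H2",
        "provenance": "theoretical maximum cumulative H2 yield of aqueous "
                      "oxidation (serpentinization) of Enceladus' reduced "
                      "core minerals",
    },
    "solar_system_age": {
        "value": 4.56e9, "units": "yr",
        "provenance": "age of the solar system; integration window for the "
                      "cumulative hydrogen budget",
    },
    "ocean_volume": {
        "value": 1.70e22, "units": "cm^3",
        "provenance": "global subsurface ocean volume for a ~28.5 km mean "
                      "ocean layer thickness",
    },
    "ocean_thickness": {
        "value": 28.5, "units": "km",
        "provenance": "mean thickness of the ocean layer from shape and "
                      "libration models",
    },
    "seafloor_area": {
        "value": 1.3e11, "units": "m^2",
        "provenance": "Enceladus seafloor surface area",
    },
    "stripe_area_fraction": {
        "value": 0.09, "units": "dimensionless",
        "provenance": "fraction of the surface covered by the south-polar "
                      "tiger-stripe terrain, taken as the hydrothermally "
                      "active fraction of the seafloor",
    },
    "yield_H2": {
        "value": 0.4, "units": "g dry weight / mol H2",
        "provenance": "growth yield of Methanobacterium "
                      "thermoautotrophicum on H2/CO2 at 65 degC, pH 7.0; "
                      "insensitive to substrate concentration and "
                      "temperature",
    },
    "cell_mass": {
        "value": 2.0e-14, "units": "g / cell",
        "provenance": "dry mass of a typical methanogen-sized prokaryotic "
                      "cell",
    },
    "life_horizon": {
        "value": 3.5e9, "units": "yr",
        "provenance": "growth horizon comparable to the age of life on "
                      "Earth",
    },
}


@dataclass(frozen=True)
class HydrogenBudget:
    """Inputs of the Enceladus hydrogen budget (units in CONSTANTS)."""

    plume_release_rate_max: float = CONSTANTS["plume_release_rate_max"]["value"]
    theoretical_total_H2: float = CONSTANTS["theoretical_total_H2"]["value"]
    solar_system_age: float = CONSTANTS["solar_system_age"]["value"]
    ocean_volume: float = CONSTANTS["ocean_volume"]["value"]
    ocean_thickness: float = CONSTANTS["ocean_thickness"]["value"]
    seafloor_area: float = CONSTANTS["seafloor_area"]["value"]
    stripe_area_fraction: float = CONSTANTS["stripe_area_fraction"]["value"]

    def __post_init__(self) -> None:
        for name in ("plume_release_rate_max", "theoretical_total_H2",
                     "solar_system_age", "ocean_volume", "ocean_thickness",
                     "seafloor_area", "stripe_area_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.plume_release_rate_max * self.solar_system_age
                > self.theoretical_total_H2):
            raise ValueError(
                "plume release over the solar-system age exceeds the "
                "theoretical total hydrogen yield"
            )


@dataclass(frozen=True)
class GrowthParameters:
    """Monod growth parameters.

    ``mu_max`` and ``Ks`` are needed only by the ODE path; no measured
    values exist for the Enceladus setting, so the defaults are
    order-of-magnitude placeholders for hydrogenotrophic methanogens and
    the headline estimates use the supply-limited linear solution, which
    does not depend on them.
    """

    Y: float = CONSTANTS["yield_H2"]["value"]          # g dry weight / mol H2
    cell_mass: float = CONSTANTS["cell_mass"]["value"]  # g / cell
    X0: float = CONSTANTS["cell_mass"]["value"]         # 1 cell/cm^3 in mass units
    mu_max: float = 0.5        # yr^-1, placeholder
    Ks: float = 1.0e-12        # mol/cm^3, placeholder

    def __post_init__(self) -> None:
        if self.Y < 0:
            raise ValueError("Y must be >= 0")
        if self.cell_mass <= 0:
            raise ValueError("cell_mass must be positive")
        if self.X0 < 0:
            raise ValueError("X0 must be >= 0")


@dataclass
class GrowthTrajectory:
    """Time series of substrate, biomass and cell concentration."""

    times: np.ndarray        # yr
    S: np.ndarray            # mol H2 / cm^3 (cumulative consumed, linear path)
    X: np.ndarray            # g dry weight / cm^3
    cells: np.ndarray        # cells / cm^3
    scenario: str = ""

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.S) == len(self.X) == len(self.cells) == n):
            raise ValueError("trajectory arrays must share one length")


@dataclass(frozen=True)
class SupplyRateResult:
    """Volumetric H2 supply rate with its budget intermediates."""

    St: float                      # mol H2 cm^-3 yr^-1
    plume_release_total: float     # mol vented over the solar-system age
    ocean_remaining_total: float   # mol left for the ocean

    def to_dict(self) -> dict:
        return {
            "St_mol_per_cm3_yr": self.St,
            "plume_release_total_mol": self.plume_release_total,
            "ocean_remaining_total_mol": self.ocean_remaining_total,
        }


def specific_growth_rate(params: GrowthParameters, S: float | np.ndarray):
    """Monod specific growth rate mu(S) = mu_max * S / (Ks + S), yr^-1."""
    S = np.maximum(S, 0.0)
    return params.mu_max * S / (params.Ks + S)


def default_budget() -> HydrogenBudget:
    return HydrogenBudget()


def default_growth_parameters() -> GrowthParameters:
    return GrowthParameters()


def hydrogen_supply_rate(budget: HydrogenBudget) -> SupplyRateResult:
    """Constant volumetric H2 supply rate from the cumulative budget.

    S_t = (total serpentinization yield - plume losses) /
          (solar-system age * ocean volume).
    """
    released = budget.plume_release_rate_max * budget.solar_system_age
    remaining = budget.theoretical_total_H2 - released
    if remaining < 0:
        raise ValueError("negative remaining hydrogen in the budget")
    St = remaining / (budget.solar_system_age * budget.ocean_volume)
    return SupplyRateResult(
        St=St, plume_release_total=released, ocean_remaining_total=remaining
    )


def cells_from_biomass(X: np.ndarray | float, cell_mass: float) -> np.ndarray | float:
    """Convert dry biomass concentration (g/cm^3) to cells/cm^3."""
    if cell_mass <= 0:
        raise ValueError("cell_mass must be positive")
    return X / cell_mass


def default_time_grid(
    t_min: float = 1.0e6,
    t_max: float = CONSTANTS["life_horizon"]["value"],
    n: int = 200,
) -> np.ndarray:
    """Logarithmic time grid for trajectory output (yr)."""
    return np.logspace(math.log10(t_min), math.log10(t_max), n)


def linear_growth(
    params: GrowthParameters, St: float, t_grid: np.ndarray, scenario: str = ""
) -> GrowthTrajectory:
    """Supply-limited linear solution X(t) = X0 + Y * S_t * t.

    Assumes cells consume hydrogen exactly as fast as it is supplied; the
    S column reports the cumulative substrate routed through the culture,
    S_t * t.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
        raise ValueError("t_grid must be non-negative and non-decreasing")
    X = params.X0 + params.Y * St * t
    return GrowthTrajectory(
        times=t,
        S=St * t,
        X=X,
        cells=cells_from_biomass(X, params.cell_mass),
        scenario=scenario,
    )


def monod_ode(
    params: GrowthParameters,
    S0: float,
    supply: float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 0.0,
    scenario: str = "monod",
) -> GrowthTrajectory:
    """Integrate the full Monod system with a constant substrate supply.

    dX/dt = mu_max * S/(Ks+S) * X
    dS/dt = supply - (1/Y) * mu_max * S/(Ks+S) * X

    (The growth equation is used with a positive sign: biomass increases
    as substrate is consumed, consistent with the yield relation
    dX = -Y dS at zero supply.)  Substrate is clamped at zero inside the
    right-hand side; a drift below zero beyond integrator tolerance is an
    error.
    """
    if S0 < 0:
        raise ValueError("S0 must be >= 0")
    if params.mu_max <= 0 or params.Ks <= 0 or params.Y <= 0:
        raise ValueError("mu_max, Ks and Y must be positive for the ODE path")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be non-negative and strictly increasing")
    if atol == 0.0:
        atol = rtol * max(S0, params.X0, params.Ks, 1e-30)

    def rhs(_t, y):
        X, S = y
        mu = specific_growth_rate(params, S)
        return [mu * X, supply - mu * X / params.Y]

    t0 = 0.0 if t[0] > 0 else t[0]
    sol = solve_ivp(
        rhs, (t0, t[-1]), [params.X0, S0], t_eval=t,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"Monod ODE integration failed: {sol.message}")
    X, S = sol.y
    neg_tol = 1e-6 * max(S0, supply * t[-1], params.Ks)
    if np.any(S < -neg_tol):
        raise RuntimeError("substrate went negative beyond tolerance")
    S = np.clip(S, 0.0, None)
    return GrowthTrajectory(
        times=t, S=S, X=X,
        cells=cells_from_biomass(X, params.cell_mass),
        scenario=scenario,
    )


def scenario_concentration(
    params: GrowthParameters,
    budget: HydrogenBudget,
    scenario: str,
    t: float,
) -> dict:
    """Cell concentration after time ``t`` under one spatial scenario.

    ``full_ocean`` feeds the whole-ocean supply rate to the linear
    solution; ``hydrothermal`` scales the supply by the tiger-stripe area
    fraction, confining harvestable hydrogen to the water column above the
    hydrothermally active seafloor.  Returns the concentration and its
    nearest order of magnitude, round(log10).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    rate = hydrogen_supply_rate(budget)
    if scenario == "full_ocean":
        St = rate.St
    elif scenario == "hydrothermal":
        St = rate.St * budget.stripe_area_fraction
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected 'full_ocean' or "
            f"'hydrothermal'"
        )
    traj = linear_growth(params, St, np.array([0.0, t]), scenario=scenario)
    conc = float(traj.cells[-1])
    return {
        "scenario": scenario,
        "t_yr": t,
        "St_mol_per_cm3_yr": St,
        "cells_per_cm3": conc,
        "order_of_magnitude": int(round(math.log10(conc))) if conc > 0 else None,
        "X_g_per_cm3": float(traj.X[-1]),
    }
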