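"""Overlay of Enceladus ocean condition intervals on fitted response curves.

Cassini-era measurements and models bound the plausible conditions of
Enceladus' subsurface ocean: salinity 5–40 PSU (plume-source lower bound to
the hydrothermally processed upper bound), ascending hydrothermal current
velocities of 0.01–0.05 m/s, temperatures from the ~0 °C ambient ocean up
to the >=50 °C water–rock interaction zones, and silica concentrations of
up to ~2500 µM inferred from E-ring silica nanograins.  Intersecting these
intervals with the suitable ranges of an Earth-trained envelope model asks
whether the macroscale conditions associated with methanogen occurrences
on Earth exist somewhere in that ocean.

Verdicts are a total function of the two intervals: ``compatible`` when
the whole Enceladus interval lies inside the Earth suitable range,
``incompatible`` when they do not intersect at all, ``partially
compatible`` otherwise.

Units are carried explicitly and never converted silently; a unit mismatch
between a condition and a response curve is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .niche_envelope import ResponseCurve

__all__ = [
    "ConditionInterval",
    "VariableOverlap",
    "OverlapReport",
    "default_enceladus_conditions",
    "overlay",
]


@dataclass(frozen=True)
class ConditionInterval:
    """One published environmental interval for Enceladus' ocean."""

    variable: str
    lower: float
    upper: float
    units: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"{self.variable}: lower {self.lower} > upper {self.upper}"
            )


@dataclass(frozen=True)
class VariableOverlap:
    variable: str
    units: str
    suitable_range: tuple[float, float]
    enceladus_interval: tuple[float, float]
    intersection: tuple[float, float] | None
    max_suitability: float
    verdict: str  # compatible | partially compatible | incompatible

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "units": self.units,
            "suitable_range": list(self.suitable_range),
            "enceladus_interval": list(self.enceladus_interval),
            "intersection": None if self.intersection is None
            else list(self.intersection),
            "max_suitability": self.max_suitability,
            "verdict": self.verdict,
        }


@dataclass
class OverlapReport:
    overlaps: dict[str, VariableOverlap]

    def verdict(self, variable: str) -> str:
        return self.overlaps[variable].verdict

    def to_dict(self) -> dict:
        return {v: o.to_dict() for v, o in self.overlaps.items()}

    def to_table(self) -> str:
        lines = [
            f"{'variable':<18}{'suitable range':<22}{'Enceladus':<20}"
            f"{'intersection':<20}{'verdict'}"
        ]
        for o in self.overlaps.values():
            inter = ("—" if o.intersection is None
                     else f"[{o.intersection[0]:g}, {o.intersection[1]:g}]")
            lines.append(
                f"{o.variable:<18}"
                f"[{o.suitable_range[0]:g}, {o.suitable_range[1]:g}] {o.units:<6}"
                f"[{o.enceladus_interval[0]:g}, {o.enceladus_interval[1]:g}]"
                f"{'':<6}{inter:<20}{o.verdict}"
            )
        return "\n".join(lines)


def default_enceladus_conditions() -> list[ConditionInterval]:
    """The published condition intervals for Enceladus' subsurface ocean.

    Temperature spans the full ambient-to-vent gradient (0 to 50 °C):
    water–rock interaction zones must reach at least ~50 °C, while the
    bulk ocean sits near 0 °C, and organisms could occupy anywhere along
    that gradient.  The silicate interval follows the µM reading of the
    E-ring silica constraint (up to 2500 µM) with lower bound 0.
    """
    return [
        ConditionInterval(
            "salinity", 5.0, 40.0, "PSU",
            "plume-source salinity lower bound to hydrothermal-zone upper "
            "bound inferred from Cassini plume and E-ring ice grain "
            "compositions",
        ),
        ConditionInterval(
            "current_velocity", 0.01, 0.05, "m/s",
            "estimated velocity of hydrothermally driven ascending currents "
            "transporting material from the seafloor to the ice shell",
        ),
        ConditionInterval(
            "temperature", 0.0, 50.0, "degC",
            "ambient ocean (~0 degC) up to the >=50 degC water-rock "
            "interaction zones required by plume chemistry; organisms may "
            "occupy any point of the gradient",
        ),
        ConditionInterval(
            "silicate", 0.0, 2500.0, "uM",
            "up to ~2500 uM dissolved silica inferred from E-ring silica "
            "nanograins (also quoted as >2000 umol/m3 in parts of the "
            "literature; no silent unit conversion is applied)",
        ),
    ]


def _interval_intersection(
    a: tuple[float, float], b: tuple[float, float]
) -> tuple[float, float] | None:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def _max_score_on_interval(curve: ResponseCurve, lo: float, hi: float) -> float:
    """Maximum marginal suitability attained on [lo, hi]."""
    inside = (curve.values >= lo) & (curve.values <= hi)
    candidates = list(curve.scores[inside])
    # interpolated endpoints, in case the interval falls between grid points
    candidates.append(float(curve.score_at(lo)))
    candidates.append(float(curve.score_at(hi)))
    return float(max(candidates))


def overlay(
    curves: list[ResponseCurve], conditions: list[ConditionInterval]
) -> OverlapReport:
    """Intersect each condition interval with its matching response curve.

    Every condition must have a response curve of the same variable name;
    units, when present on both sides, must agree exactly.
    """
    by_var = {c.variable: c for c in curves}
    overlaps: dict[str, VariableOverlap] = {}
    for cond in sorted(conditions, key=lambda c: c.variable):
        if cond.variable not in by_var:
            raise KeyError(
                f"no response curve for condition variable {cond.variable!r}"
            )
        curve = by_var[cond.variable]
        if curve.units and cond.units and curve.units != cond.units:
            raise ValueError(
                f"{cond.variable}: unit mismatch between curve "
                f"({curve.units!r}) and condition ({cond.units!r})"
            )
        suitable = curve.suitable_range
        enc = (cond.lower, cond.upper)
        inter = _interval_intersection(suitable, enc)
        if inter is None:
            verdict = "incompatible"
            max_suit = 0.0
        else:
            contained = suitable[0] <= enc[0] and enc[1] <= suitable[1]
            verdict = "compatible" if contained else "partially compatible"
            max_suit = _max_score_on_interval(curve, enc[0], enc[1])
        overlaps[cond.variable] = VariableOverlap(
            variable=cond.variable,
            units=cond.units,
            suitable_range=(float(suitable[0]), float(suitable[1])),
            enceladus_interval=enc,
            intersection=inter,
            max_suitability=max_suit,
            verdict=verdict,
        )
    return OverlapReport(overlaps=overlaps)
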