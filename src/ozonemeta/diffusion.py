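"""Fick's-law gas transport estimates in soft tissue.

First law: diffusive flux J = −D · dC/dx (mol·m⁻²·s⁻¹) for a gas with
diffusion coefficient D (m²/s) down a concentration gradient dC/dx.

Second law, order-of-magnitude form: the characteristic time for a gas to
diffuse across a path of length x in one dimension is t ≈ x²/(2D). A 3-D
variant x²/(6D) is exposed for sensitivity checks only.

All computation is in SI units (metres, seconds); reporting helpers convert
to minutes. Published worked examples for a 3 mm path print the same
mantissas against a "min" label although x²/(2D) evaluates to thousands of
seconds — reporting code therefore carries both values and the
``EQ12-UNITS`` discrepancy code rather than adjudicating.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "GasSpecies",
    "DiffusionScenario",
    "FluxQuery",
    "fick_flux",
    "characteristic_time",
    "arrival_table",
    "observation_consistency",
    "EQ12_UNITS_NOTE",
]

EQ12_UNITS_NOTE = (
    "EQ12-UNITS: x^2/(2D) at x = 3 mm evaluates to ~2.25e3 s (37.5 min) for O2, "
    "published as '2.25 min'; numeric mantissas reported in units of 10^3 s."
)


@dataclass(frozen=True)
class GasSpecies:
    """A gas with its diffusion coefficient in soft tissue at 37 °C."""

    name: str
    diffusion_coefficient: float  # m^2/s

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise ValidationError(
                f"diffusion coefficient must be > 0, got {self.diffusion_coefficient}"
            )


@dataclass(frozen=True)
class DiffusionScenario:
    """A gas crossing a path length with its characteristic time."""

    gas: GasSpecies
    path_length: float  # m
    characteristic_time: float  # s

    def __post_init__(self) -> None:
        if self.path_length < 0 or self.characteristic_time < 0:
            raise ValidationError("path length and time must be >= 0")


@dataclass(frozen=True)
class FluxQuery:
    """A gas plus a spatial concentration gradient (mol·m⁻³ per m)."""

    gas: GasSpecies
    concentration_gradient: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.concentration_gradient):
            raise ValidationError("concentration gradient must be finite")


def fick_flux(q: FluxQuery) -> float:
    """Diffusive flux J = −D·dC/dx; the sign opposes the gradient."""
    return -q.gas.diffusion_coefficient * q.concentration_gradient


def characteristic_time(x: float, gas: GasSpecies, *, geometry: str = "1d") -> float:
    """Characteristic diffusion time across distance ``x`` in seconds.

    ``geometry="1d"`` (default, the published convention) gives x²/(2D);
    ``"3d"`` gives x²/(6D).
    """
    if x < 0:
        raise ValidationError(f"distance must be >= 0, got {x}")
    if geometry == "1d":
        factor = 2.0
    elif geometry == "3d":
        factor = 6.0
    else:
        raise ValidationError(f"unknown geometry {geometry!r}")
    return x**2 / (factor * gas.diffusion_coefficient)


def arrival_table(
    distances: list[float],
    gases: list[GasSpecies],
    *,
    geometry: str = "1d",
) -> pd.DataFrame:
    """Cartesian grid of characteristic times for each (gas, distance) pair."""
    if not distances or not gases:
        raise ValidationError("distances and gases must be nonempty")
    rows = []
    for gas in gases:
        for x in distances:
            t = characteristic_time(x, gas, geometry=geometry)
            rows.append(
                {
                    "gas": gas.name,
                    "D_m2_per_s": gas.diffusion_coefficient,
                    "distance_m": x,
                    "time_s": t,
                    "time_min": t / 60.0,
                    "time_ks": t / 1000.0,
                }
            )
    return pd.DataFrame(rows)


def observation_consistency(
    t_predicted: float,
    schedule: list[float],
    window_pad: float = 0.0,
) -> list[str]:
    """Classify each scheduled scan time against a predicted arrival time.

    A scan at time s is "within_window" when the pad is positive and
    |s − t_predicted| <= pad (the boundary |s − t| = pad counts as within);
    otherwise it is "before_arrival" when s < t_predicted and
    "after_arrival" when s >= t_predicted (a scan exactly at a zero-pad
    arrival time counts as after). Pure interval arithmetic, no physics.
    """
    if window_pad < 0:
        raise ValidationError(f"window pad must be >= 0, got {window_pad}")
    if any(s < 0 for s in schedule):
        raise ValidationError("scan times must be >= 0")
    if sorted(schedule) != list(schedule):
        raise ValidationError("schedule must be sorted ascending")
    verdicts = []
    for s in schedule:
        if window_pad > 0 and abs(s - t_predicted) <= window_pad:
            verdicts.append("within_window")
        elif s < t_predicted:
            verdicts.append("before_arrival")
        else:
            verdicts.append("after_arrival")
    return verdicts
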