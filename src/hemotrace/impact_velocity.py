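"""Impact speed from stain width via the maximum-spreading interpolation.

An impacting droplet spreads to a maximum diameter D_max set by the balance
of inertia against capillary and viscous resistance.  With Weber number
We = rho*D0*v^2/sigma, Reynolds number Re = rho*D0*v/eta and impact number
P = We*Re^(-2/5), the spreading ratio follows the interpolation

    D_max / D0 = Re^(1/5) * sqrt(P) / (A + sqrt(P)),       A = 1.24,

which bridges the capillary (We^(1/2)) and viscous (Re^(1/5)) regimes.  The
ratio is strictly increasing in v, so measuring the stain width W_max and
knowing D0 (from the stain volume) determines the impact speed uniquely;
:func:`solve_impact_velocity` performs that numerical inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BloodProperties",
    "DimensionlessNumbers",
    "NoSolutionError",
    "dimensionless_numbers",
    "max_spread_ratio",
    "solve_impact_velocity",
]

V_BRACKET = (0.01, 100.0)  # m/s search bracket for the inversion


class NoSolutionError(ValueError):
    """The requested spreading ratio is unattainable within the velocity bracket."""


@dataclass(frozen=True)
class BloodProperties:
    """Fluid constants of whole blood.

    Defaults are literature values for whole blood at typical hematocrit:
    density 1060 kg/m3, (high-shear) viscosity 4.8 mPa s, surface tension
    0.060 N/m.  ``spreading_A`` is the fitting constant of the spreading
    interpolation.
    """

    density: float = 1060.0  # kg/m^3
    viscosity: float = 4.8e-3  # Pa s
    surface_tension: float = 0.060  # N/m
    spreading_A: float = 1.24
    hematocrit: float = 0.44

    def __post_init__(self) -> None:
        for name in ("density", "viscosity", "surface_tension", "spreading_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DimensionlessNumbers:
    we: float
    re: float
    p: float


def dimensionless_numbers(
    props: BloodProperties, d0_m: float, v_m_s: float
) -> DimensionlessNumbers:
    """Weber, Reynolds and impact numbers for a droplet of diameter d0 at speed v."""
    if d0_m <= 0:
        raise ValueError("droplet diameter must be positive")
    if v_m_s < 0:
        raise ValueError("speed must be non-negative")
    we = props.density * d0_m * v_m_s**2 / props.surface_tension
    re = props.density * d0_m * v_m_s / props.viscosity
    p = we * re ** (-0.4) if re > 0 else 0.0
    return DimensionlessNumbers(we=we, re=re, p=p)


def max_spread_ratio(nums: DimensionlessNumbers, a: float = 1.24) -> float:
    """Maximum spreading ratio xi = D_max/D0 from the regime interpolation."""
    if nums.re <= 0:
        raise NoSolutionError("spreading undefined at zero Reynolds number")
    sqrt_p = math.sqrt(nums.p)
    return nums.re ** 0.2 * sqrt_p / (a + sqrt_p)


def _spread_diameter_mm(v: float, d0_mm: float, props: BloodProperties) -> float:
    nums = dimensionless_numbers(props, d0_mm * 1e-3, v)
    return max_spread_ratio(nums, props.spreading_A) * d0_mm


def solve_impact_velocity(
    w_max_mm: float, d0_mm: float, props: BloodProperties | None = None
) -> float:
    """Impact speed (m/s) such that the droplet spreads to width ``w_max_mm``.

    Inverts the spreading law by bracketed root-finding over
    v in [0.01, 100] m/s; the spreading ratio is strictly increasing in v so
    the root is unique.  Raises :class:`NoSolutionError` when the measured
    width is below the smallest or above the largest attainable spread in the
    bracket (such stains are unsuitable for velocity inference).
    """
    if w_max_mm <= 0 or d0_mm <= 0:
        raise ValueError("stain width and droplet diameter must be positive")
    if props is None:
        props = BloodProperties()
    lo, hi = V_BRACKET
    f = lambda v: _spread_diameter_mm(v, d0_mm, props) - w_max_mm
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0:
        raise NoSolutionError(
            f"stain width {w_max_mm} mm below attainable spread "
            f"({_spread_diameter_mm(lo, d0_mm, props):.3g} mm at v = {lo} m/s)"
        )
    if f_hi < 0:
        raise NoSolutionError(
            f"stain width {w_max_mm} mm exceeds spread at v = {hi} m/s "
            f"({_spread_diameter_mm(hi, d0_mm, props):.3g} mm)"
        )
    return float(brentq(f, lo, hi, rtol=1e-9, xtol=1e-12))
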