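"""Extreme-fiber stresses and the yield-based safety factor.

Normal stress combines the (constant) axial force with the located
bending-moment extremum:

    sigma_MAX1 = N/A - M_oMAX/W_o,    sigma_MAX2 = N/A + M_oMAX/W_o

Peak shear is ``shear_factor * T_MAX / A`` (4/3 solid, 2 cannulated) and
the safety factor is ``S_Re = Re / max(|sigma_MAX1|, |sigma_MAX2|)``.
Compression is reported negative; the safety factor uses magnitudes, so
the sign convention is reporting-only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sections import SectionProperties

__all__ = [
    "StressSummary",
    "normal_stress_extremes",
    "max_shear_stress",
    "safety_factor",
    "stress_summary",
    "UndefinedSafetyError",
]


class UndefinedSafetyError(ValueError):
    """Safety factor requested for an identically unstressed state."""


@dataclass(frozen=True)
class StressSummary:
    """Stress extremes [Pa] and the dimensionless safety factor.

    ``von_mises`` combines the separately-located normal and shear peaks
    conservatively (they need not be co-located); it is informational
    only and never enters ``S_Re``.
    """

    sigma_MAX1: float
    sigma_MAX2: float
    tau_MAX: float
    sigma_MAX_abs: float
    S_Re: float
    unsafe: bool
    von_mises: float


def normal_stress_extremes(N: float, A: float, M_oMAX: float, W_o: float) -> tuple[float, float]:
    """Extreme-fiber normal stresses (sigma_MAX1, sigma_MAX2)."""
    if not (A > 0 and W_o > 0):
        raise ValueError(f"A and W_o must be positive (A={A}, W_o={W_o})")
    return N / A - M_oMAX / W_o, N / A + M_oMAX / W_o


def max_shear_stress(T_MAX: float, props: SectionProperties) -> float:
    """Peak transverse shear stress shear_factor·T_MAX/A."""
    if not props.A > 0:
        raise ValueError(f"A must be positive, got {props.A}")
    return props.shear_factor * T_MAX / props.A


def safety_factor(Re: float, sigma_MAX1: float, sigma_MAX2: float) -> float:
    """S_Re = Re / max(|sigma_MAX1|, |sigma_MAX2|)."""
    if not Re > 0:
        raise ValueError(f"Re must be positive, got {Re}")
    sig = max(abs(sigma_MAX1), abs(sigma_MAX2))
    if sig == 0.0:
        raise UndefinedSafetyError("both stress extremes are zero; safety factor undefined")
    return Re / sig


def stress_summary(
    N: float, T_MAX: float, M_oMAX: float, props: SectionProperties, Re: float
) -> StressSummary:
    """Full stress/safety record from field extrema and section properties."""
    s1, s2 = normal_stress_extremes(N, props.A, M_oMAX, props.W_o)
    tau = max_shear_stress(abs(T_MAX), props)
    s_re = safety_factor(Re, s1, s2)
    sig = max(abs(s1), abs(s2))
    return StressSummary(
        sigma_MAX1=s1,
        sigma_MAX2=s2,
        tau_MAX=tau,
        sigma_MAX_abs=sig,
        S_Re=s_re,
        unsafe=s_re <= 1.0,
        von_mises=(sig**2 + 3.0 * tau**2) ** 0.5,
    )
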