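"""Patient/stance parameters -> per-screw force components.

The quasi-dynamic stance force is ``F_m = m * k_m * k_dyn * g`` (single-leg
stance; dynamic effects folded into ``k_dyn``).  It is shared between the
screws through the division coefficient ``n`` and split along/across the
screw axis by the insertion angle ``alpha``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["G", "LoadCase", "ScrewForces", "total_force", "per_screw_forces", "screw_forces"]

#: gravity acceleration [m/s²]; fixed, not configurable.
G = 9.807

# nominal bands; values outside warn but do not fail
_K_M_BAND = (0.78, 0.82)
_K_DYN_BAND = (1.0, 4.0)
_N_BAND = (2.0, 3.0)
_ALPHA_BAND = (5.0, 80.0)


class LoadRangeWarning(UserWarning):
    """A load parameter lies outside its usual physical band."""


@dataclass(frozen=True)
class LoadCase:
    """One loading scenario.

    m
        patient mass [kg]
    k_m
        body-minus-one-limb mass fraction (nominally 0.78–0.82)
    k_dyn
        dynamic force coefficient (nominally 1–4)
    n
        force-division coefficient: 3 = uniform over three screws,
        2 = unfavourable two-screw split
    alpha_deg
        screw/force angle [deg], nominally 5–80
    """

    m: float
    k_m: float
    k_dyn: float
    n: float
    alpha_deg: float

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError(f"m must be positive, got m={self.m}")
        for name, value, band in (
            ("k_m", self.k_m, _K_M_BAND),
            ("k_dyn", self.k_dyn, _K_DYN_BAND),
            ("n", self.n, _N_BAND),
            ("alpha_deg", self.alpha_deg, _ALPHA_BAND),
        ):
            if not band[0] <= value <= band[1]:
                warnings.warn(
                    f"{name}={value} outside usual band {band}",
                    LoadRangeWarning,
                    stacklevel=2,
                )


@dataclass(frozen=True)
class ScrewForces:
    """Total and per-screw force components [N].

    F_m total quasi-dynamic force; F = F_m/n per screw;
    F1 = F·cos(alpha) transverse; F2 = F·sin(alpha) axial.
    """

    F_m: float
    F: float
    F1: float
    F2: float


def total_force(case: LoadCase) -> float:
    """Total quasi-dynamic force F_m = m·k_m·k_dyn·g [N]."""
    return case.m * case.k_m * case.k_dyn * G


def per_screw_forces(F_m: float, n: float, alpha_deg: float) -> ScrewForces:
    """Split F_m into per-screw transverse (F1) and axial (F2) components."""
    if not n > 0:
        raise ValueError(f"n must be positive, got n={n}")
    if not 0.0 <= alpha_deg <= 90.0:
        raise ValueError(f"alpha_deg must lie in [0, 90], got {alpha_deg}")
    F = F_m / n
    alpha = math.radians(alpha_deg)
    return ScrewForces(F_m=F_m, F=F, F1=F * math.cos(alpha), F2=F * math.sin(alpha))


def screw_forces(case: LoadCase) -> ScrewForces:
    """Convenience: :func:`total_force` followed by :func:`per_screw_forces`."""
    return per_screw_forces(total_force(case), case.n, case.alpha_deg)
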