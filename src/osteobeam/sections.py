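"""Cross-section geometry and material definitions.

All quantities are SI internally (m, N, Pa).  User-facing unit conversion
(mm, MPa, N·mm) happens exactly once, in :mod:`osteobeam.config`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CrossSection",
    "Material",
    "SectionProperties",
    "section_properties",
    "CATALOG",
    "SectionError",
]

FULL = "full"
CANNULATED = "cannulated"

#: peak-shear coefficients: parabolic shear distribution over a solid circle
#: peaks at 4/3 of the mean; a thin-walled-style annular bore doubles it.
SHEAR_FACTOR_FULL = 4.0 / 3.0
SHEAR_FACTOR_CANNULATED = 2.0


class SectionError(ValueError):
    """Invalid cross-section geometry (names the offending field)."""


@dataclass(frozen=True)
class CrossSection:
    """Circular screw shank cross-section, solid or with a central bore.

    Parameters
    ----------
    kind:
        ``"full"`` (solid) or ``"cannulated"`` (central bore for a guide
        wire).
    D:
        Shank (outer) diameter [m].  The thread is ignored: the shank
        diameter approximates the mean diameter of the threaded part.
    d:
        Bore (inner) diameter [m], cannulated sections only.
    """

    kind: str
    D: float
    d: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (FULL, CANNULATED):
            raise SectionError(f"kind must be 'full' or 'cannulated', got {self.kind!r}")
        if not self.D > 0:
            raise SectionError(f"D must be positive, got D={self.D}")
        if self.kind == CANNULATED:
            if self.d is None or not self.d > 0:
                raise SectionError(f"d must be positive for a cannulated section, got d={self.d}")
            if self.d >= self.D:
                raise SectionError(f"d must be smaller than D, got d={self.d} >= D={self.D}")
        elif self.d is not None:
            raise SectionError("d is only meaningful for cannulated sections")


@dataclass(frozen=True)
class Material:
    """Linear isotropic material: Young's modulus E and yield strength Re [Pa]."""

    E: float
    Re: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise SectionError(f"E must be positive, got E={self.E}")
        if not self.Re > 0:
            raise SectionError(f"Re must be positive, got Re={self.Re}")


@dataclass(frozen=True)
class SectionProperties:
    """Derived section quantities for bending/shear stress evaluation.

    A
        cross-sectional area [m²]
    J_ZT
        second moment of area about the bending axis [m⁴]
    W_o
        section modulus in bending, ``J_ZT / (D/2)`` [m³]
    shear_factor
        dimensionless peak-shear coefficient (4/3 solid, 2 cannulated)
    """

    A: float
    J_ZT: float
    W_o: float
    shear_factor: float


def section_properties(section: CrossSection) -> SectionProperties:
    """Compute area, second moment, section modulus and shear factor.

    Solid circle:  A = πD²/4,  J = πD⁴/64,  W_o = πD³/32.
    Annulus:       A = π(D²−d²)/4,  J = π(D⁴−d⁴)/64,  W_o = π(D⁴−d⁴)/(32D).

    Works elementwise on array-valued ``D``/``d`` as well (used by the
    Monte-Carlo engine); the dataclass then holds ndarrays.
    """
    D = section.D
    if section.kind == FULL:
        A = math.pi * D**2 / 4.0
        J = math.pi * D**4 / 64.0
        shear = SHEAR_FACTOR_FULL
    else:
        d = section.d
        A = math.pi * (D**2 - d**2) / 4.0
        J = math.pi * (D**4 - d**4) / 64.0
        shear = SHEAR_FACTOR_CANNULATED
    W_o = J / (D / 2.0)
    return SectionProperties(A=A, J_ZT=J, W_o=W_o, shear_factor=shear)


def annulus_properties(D: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (A, J, W_o) for outer diameter D and bore d (d=0 → solid)."""
    D = np.asarray(D, dtype=float)
    d = np.asarray(d, dtype=float)
    A = np.pi * (D**2 - d**2) / 4.0
    J = np.pi * (D**4 - d**4) / 64.0
    return A, J, J / (D / 2.0)


#: Built-in shank geometries used by the worked examples.  Only these two
#: entries are certain; anything added later must be flagged unverified.
CATALOG: dict[str, CrossSection] = {
    "4.5-full": CrossSection(kind=FULL, D=4.5e-3),
    "5.0-cannulated": CrossSection(kind=CANNULATED, D=5.0e-3, d=1.8e-3),
}
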