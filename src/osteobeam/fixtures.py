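"""Seeded generator of admissible, solvable parameter sets.

Used by the test-suite and the ``fixtures`` CLI command.  The two
reference geometries (4.5 mm solid steel, 5/1.8 mm cannulated Ti6Al4V)
carry documented *placeholder* load/foundation values — they exercise the
reference shank geometries but are not a transcription of any published
input set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pipeline import CaseParams, build_model
from .sections import CANNULATED, FULL, CrossSection, section_properties
from .solver import OvercriticalAxialForceError

__all__ = ["Fixture", "generate_fixtures"]


@dataclass(frozen=True)
class Fixture:
    name: str
    params: CaseParams
    tags: tuple[str, ...]


_STEEL = {"E": 200e9, "Re": 1000e6}
_TI6AL4V = {"E": 110e9, "Re": 880e6}


def _reference_params(section: CrossSection, mat: dict, **overrides) -> CaseParams:
    base = dict(
        m=95.0,
        k_m=0.80,
        k_dyn=1.2,
        n=2.0,
        alpha_deg=50.0,
        section=section,
        E=mat["E"],
        Re=mat["Re"],
        L=0.090,
        L1=0.030,
        L2=0.060,
        k=2.0e7,
    )
    base.update(overrides)
    return CaseParams(**base)


def generate_fixtures(seed: int) -> list[Fixture]:
    """At least ten solvable fixtures spanning the admissible ranges.

    Coverage: alpha over [5, 80] deg, both section kinds, foundation
    stiffness over three decades, a symmetric load placement, an
    axial-force-free case, and a near-overcritical axial force
    (N² = 0.99·4·EJ·k) for conditioning tests.
    """
    rng = np.random.default_rng(seed)
    fixtures: list[Fixture] = []

    full_ref = _reference_params(CrossSection(kind=FULL, D=4.5e-3), _STEEL)
    cann_ref = _reference_params(CrossSection(kind=CANNULATED, D=5.0e-3, d=1.8e-3), _TI6AL4V)
    fixtures.append(Fixture("full-steel-reference", full_ref, ("reference", "placeholder-inputs")))
    fixtures.append(Fixture("cannulated-ti-reference", cann_ref, ("reference", "placeholder-inputs")))
    fixtures.append(
        Fixture(
            "symmetric-placement",
            _reference_params(CrossSection(kind=FULL, D=4.5e-3), _STEEL, L1=0.025, L2=0.065),
            ("symmetric",),
        )
    )
    fixtures.append(
        Fixture(
            "axial-free",
            _reference_params(CrossSection(kind=FULL, D=4.5e-3), _STEEL, N_override=0.0),
            ("axial-free",),
        )
    )
    # near-overcritical compression: N² = 0.99·4·EJ·k
    sec = CrossSection(kind=FULL, D=4.0e-3)
    props = section_properties(sec)
    k_soft = 1.0e6
    n_crit = -math.sqrt(0.99 * 4.0 * _STEEL["E"] * props.J_ZT * k_soft)
    fixtures.append(
        Fixture(
            "near-overcritical",
            _reference_params(sec, _STEEL, k=k_soft, N_override=n_crit),
            ("near-overcritical",),
        )
    )

    alphas = np.concatenate([[5.0, 80.0], rng.uniform(5.0, 80.0, 5)])
    k_decades = [1.0e6, 1.0e7, 1.0e8, 1.0e9]
    for i, alpha in enumerate(alphas):
        for _ in range(200):  # resample until the draw is sub-critical
            kind = FULL if rng.random() < 0.5 else CANNULATED
            D = rng.uniform(3.0e-3, 6.5e-3)
            section = (
                CrossSection(kind=FULL, D=D)
                if kind == FULL
                else CrossSection(kind=CANNULATED, D=D, d=rng.uniform(0.2, 0.45) * D)
            )
            L = rng.uniform(0.060, 0.120)
            u1 = rng.uniform(0.15, 0.45)
            u2 = rng.uniform(u1 + 0.15, 0.90)
            mat = _STEEL if rng.random() < 0.5 else _TI6AL4V
            params = CaseParams(
                m=rng.uniform(50.0, 120.0),
                k_m=rng.uniform(0.78, 0.82),
                k_dyn=rng.uniform(1.0, 4.0),
                n=rng.uniform(2.0, 3.0),
                alpha_deg=float(alpha),
                section=section,
                E=mat["E"],
                Re=mat["Re"],
                L=L,
                L1=u1 * L,
                L2=u2 * L,
                k=float(k_decades[i % len(k_decades)] * rng.uniform(0.5, 2.0)),
            )
            try:
                build_model(params)
            except (OvercriticalAxialForceError, ValueError):
                continue
            fixtures.append(Fixture(f"random-{i}", params, ("random",)))
            break
        else:  # pragma: no cover
            raise RuntimeError("failed to draw a sub-critical fixture")
    return fixtures
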