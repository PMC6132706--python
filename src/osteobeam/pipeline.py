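"""End-to-end deterministic case: parameters -> forces -> fields -> safety."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .loading import LoadCase, ScrewForces, screw_forces
from .sections import CrossSection, SectionProperties, section_properties
from .solver import (
    FieldSolution,
    ScrewBeamModel,
    _equilibrate,
    assemble_system,
    evaluate_fields,
    solve_constants,
)
from .stress import StressSummary, stress_summary

__all__ = ["CaseParams", "CaseResult", "build_model", "analyze"]


@dataclass(frozen=True)
class CaseParams:
    """Complete deterministic input set for one screw (SI units).

    The axial force is taken as ``N = -F2`` (compression) unless
    ``N_override`` is given (used by constructed fixtures).
    """

    m: float
    k_m: float
    k_dyn: float
    n: float
    alpha_deg: float
    section: CrossSection
    E: float
    Re: float
    L: float
    L1: float
    L2: float
    k: float
    N_override: float | None = None


@dataclass(frozen=True)
class CaseResult:
    params: CaseParams
    forces: ScrewForces
    props: SectionProperties
    model: ScrewBeamModel
    solution: FieldSolution
    stresses: StressSummary
    condition: float

    def summary_record(self) -> dict:
        """Report-unit summary (mm, N, N·mm, MPa) plus derived quantities."""
        r = self.model.roots()
        sol = self.solution
        st = self.stresses
        return {
            "v_MAX_mm": sol.v_max.value * 1e3,
            "T_MAX_N": sol.T_max.value,
            "M_oMAX_Nmm": sol.M_o_max.value * 1e3,
            "tau_MAX_MPa": st.tau_MAX * 1e-6,
            "sigma_MAX1_MPa": st.sigma_MAX1 * 1e-6,
            "sigma_MAX2_MPa": st.sigma_MAX2 * 1e-6,
            "S_Re": st.S_Re,
            "unsafe": st.unsafe,
            "x_at_v_MAX_mm": sol.v_max.x * 1e3,
            "x_at_M_oMAX_mm": sol.M_o_max.x * 1e3,
            "x_at_T_MAX_mm": sol.T_max.x * 1e3,
            "derived": {
                "F_m_N": self.forces.F_m,
                "F_N": self.forces.F,
                "F1_N": self.forces.F1,
                "F2_N": self.forces.F2,
                "N_N": self.model.N,
                "omega_R_per_m": r.omega_R,
                "omega_I_per_m": r.omega_I,
                "condition_estimate": self.condition,
            },
        }


def build_model(params: CaseParams) -> tuple[ScrewBeamModel, SectionProperties, ScrewForces]:
    """Resolve section properties and forces into the boundary-value problem."""
    props = section_properties(params.section)
    forces = screw_forces(
        LoadCase(
            m=params.m,
            k_m=params.k_m,
            k_dyn=params.k_dyn,
            n=params.n,
            alpha_deg=params.alpha_deg,
        )
    )
    N = -forces.F2 if params.N_override is None else params.N_override
    model = ScrewBeamModel(
        L=params.L,
        L1=params.L1,
        L2=params.L2,
        k=params.k,
        E=params.E,
        J_ZT=props.J_ZT,
        F1=forces.F1,
        N=N,
    )
    return model, props, forces


def analyze(params: CaseParams, n_samples_per_segment: int = 2001) -> CaseResult:
    """Run the full deterministic pipeline for one case."""
    model, props, forces = build_model(params)
    constants = solve_constants(model)
    M, B = assemble_system(model)
    Ms, _ = _equilibrate(M, B)
    condition = float(np.linalg.cond(Ms))
    solution = evaluate_fields(model, constants, n_samples_per_segment)
    stresses = stress_summary(
        N=model.N,
        T_MAX=solution.T_max.value,
        M_oMAX=solution.M_o_max.value,
        props=props,
        Re=params.Re,
    )
    return CaseResult(
        params=params,
        forces=forces,
        props=props,
        model=model,
        solution=solution,
        stresses=stresses,
        condition=condition,
    )
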