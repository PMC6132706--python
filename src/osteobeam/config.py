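"""Run configuration: YAML parsing, validation and unit conversion.

Config keys embed their units (``L_mm``, ``k_N_per_m2``, ``E_MPa``...);
this module is the single place where user units (mm, N, MPa) are
converted to the SI quantities used everywhere else in the package.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pipeline import CaseParams
from .sbra import InputDistribution
from .sections import CATALOG, CrossSection

__all__ = ["RunConfig", "load_config", "case_params", "sbra_distributions"]

MM = 1e-3
MPA = 1e6


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScrewConfig(_Block):
    """Either a catalog name or explicit kind/D_mm (and d_mm if cannulated)."""

    catalog: str | None = None
    kind: Literal["full", "cannulated"] | None = None
    D_mm: float | None = None
    d_mm: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "ScrewConfig":
        if self.catalog is not None:
            if self.catalog not in CATALOG:
                raise ValueError(f"screw.catalog: unknown entry {self.catalog!r}; have {sorted(CATALOG)}")
        elif self.kind is None or self.D_mm is None:
            raise ValueError("screw: give either catalog or kind + D_mm")
        return self

    def to_section(self) -> CrossSection:
        if self.catalog is not None:
            return CATALOG[self.catalog]
        d = self.d_mm * MM if self.d_mm is not None else None
        return CrossSection(kind=self.kind, D=self.D_mm * MM, d=d)


class LoadConfig(_Block):
    m_kg: float
    k_m: float
    k_dyn: float
    n: float
    alpha_deg: float


class BeamConfig(_Block):
    L_mm: float
    L1_mm: float
    L2_mm: float
    k_N_per_m2: float


class MaterialConfig(_Block):
    E_MPa: float
    Re_MPa: float


class SolverConfig(_Block):
    samples_per_segment: int = Field(default=2001, ge=2)


class SBRAVariableConfig(_Block):
    family: Literal["point", "uniform", "triangular", "histogram"]
    lo: float | None = None
    hi: float | None = None
    mode: float | None = None
    bin_edges: list[float] | None = None
    weights: list[float] | None = None


class SBRAConfig(_Block):
    n_draws: int = Field(default=100_000, ge=1)
    seed: int
    variables: dict[str, SBRAVariableConfig]
    hist_var: str | None = None
    hist_bins: int = Field(default=30, ge=1)


class OutputConfig(_Block):
    directory: str = "out"
    plots: bool = False


class RunConfig(_Block):
    screw: ScrewConfig
    load: LoadConfig
    beam: BeamConfig
    material: MaterialConfig
    solver: SolverConfig = SolverConfig()
    sbra: SBRAConfig | None = None
    output: OutputConfig = OutputConfig()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def case_params(cfg: RunConfig) -> CaseParams:
    """Resolve a config to SI-valued deterministic case parameters."""
    return CaseParams(
        m=cfg.load.m_kg,
        k_m=cfg.load.k_m,
        k_dyn=cfg.load.k_dyn,
        n=cfg.load.n,
        alpha_deg=cfg.load.alpha_deg,
        section=cfg.screw.to_section(),
        E=cfg.material.E_MPa * MPA,
        Re=cfg.material.Re_MPa * MPA,
        L=cfg.beam.L_mm * MM,
        L1=cfg.beam.L1_mm * MM,
        L2=cfg.beam.L2_mm * MM,
        k=cfg.beam.k_N_per_m2,
    )


#: sbra config key -> (draw-variable name, factor to SI)
_SBRA_KEYS = {
    "m_kg": ("m", 1.0),
    "k_m": ("k_m", 1.0),
    "k_dyn": ("k_dyn", 1.0),
    "n": ("n", 1.0),
    "alpha_deg": ("alpha", 1.0),
    "k_N_per_m2": ("k", 1.0),
    "E_MPa": ("E", MPA),
    "Re_MPa": ("Re", MPA),
    "D_mm": ("D", MM),
    "d_mm": ("d", MM),
    "L_mm": ("L", MM),
    "L1_mm": ("L1", MM),
    "L2_mm": ("L2", MM),
}


def sbra_distributions(cfg: RunConfig) -> list[InputDistribution]:
    """Translate the sbra variable block into SI input distributions."""
    if cfg.sbra is None:
        raise ValueError("config has no sbra block")
    dists = []
    for key, var in cfg.sbra.variables.items():
        if key not in _SBRA_KEYS:
            raise ValueError(f"sbra.variables: unknown key {key!r}; use one of {sorted(_SBRA_KEYS)}")
        name, factor = _SBRA_KEYS[key]
        scale = lambda x: None if x is None else x * factor  # noqa: E731
        dists.append(
            InputDistribution(
                name=name,
                family=var.family,
                lo=scale(var.lo),
                hi=scale(var.hi),
                mode=scale(var.mode),
                bin_edges=None if var.bin_edges is None else tuple(x * factor for x in var.bin_edges),
                weights=None if var.weights is None else tuple(var.weights),
            )
        )
    return dists
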