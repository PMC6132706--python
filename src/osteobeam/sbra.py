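"""Monte-Carlo reliability analysis of the screw pipeline.

Scalar inputs of the deterministic model are replaced by sampled
distributions; each draw runs the full pipeline and yields a reliability
function value ``RF = Re - |sigma_MAX|``.  The failure probability is the
fraction of draws with ``RF < 0``, reported with a Wilson confidence
interval.  Each variable owns its own seed stream derived from (seed,
variable name), so shifting one distribution leaves the other draws
untouched (common random numbers).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .loading import G
from .pipeline import CaseParams, analyze
from .sections import CANNULATED, CrossSection, annulus_properties
from .solver import batch_extremes

__all__ = [
    "InputDistribution",
    "ReliabilityResult",
    "sample_inputs",
    "reliability",
    "UnsolvableDrawsError",
]

#: draw-table columns understood by :func:`reliability`
VARIABLES = ("m", "k_m", "k_dyn", "n", "alpha", "k", "E", "Re", "D", "d", "L", "L1", "L2")

_ADMISSIBLE: dict[str, tuple[float, float]] = {
    "m": (0.0, np.inf),
    "k_m": (0.0, 1.0),
    "k_dyn": (0.0, np.inf),
    "n": (0.0, np.inf),
    "alpha": (0.0, 90.0),
    "k": (0.0, np.inf),
    "E": (0.0, np.inf),
    "Re": (0.0, np.inf),
    "D": (0.0, np.inf),
    "d": (0.0, np.inf),
    "L": (0.0, np.inf),
    "L1": (0.0, np.inf),
    "L2": (0.0, np.inf),
}

_BATCH_CHUNK = 4096


class UnsolvableDrawsError(RuntimeError):
    """More than the tolerated fraction of draws is overcritical."""


@dataclass(frozen=True)
class InputDistribution:
    """One stochastic input.

    family
        ``point`` (degenerate at ``lo``), ``uniform`` on (lo, hi),
        ``triangular`` on (lo, hi) with ``mode``, or ``histogram`` with
        ``bin_edges``/``weights`` (the truncated-histogram idiom; bins
        must be supplied by the user, none are invented).
    """

    name: str
    family: str
    lo: float | None = None
    hi: float | None = None
    mode: float | None = None
    bin_edges: tuple[float, ...] | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in VARIABLES:
            raise ValueError(f"unknown variable {self.name!r}; choose from {VARIABLES}")
        if self.family not in ("point", "uniform", "triangular", "histogram"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "histogram":
            if self.bin_edges is None or self.weights is None:
                raise ValueError(f"{self.name}: histogram requires bin_edges and weights")
            edges = np.asarray(self.bin_edges, dtype=float)
            w = np.asarray(self.weights, dtype=float)
            if edges.ndim != 1 or len(edges) != len(w) + 1 or np.any(np.diff(edges) <= 0):
                raise ValueError(f"{self.name}: bin_edges must be increasing, one more than weights")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError(f"{self.name}: histogram weights are not normalizable")
            support = (edges[0], edges[-1])
        else:
            if self.lo is None:
                raise ValueError(f"{self.name}: lo is required")
            if self.family == "point":
                support = (self.lo, self.lo)
            else:
                if self.hi is None or not self.hi >= self.lo:
                    raise ValueError(f"{self.name}: require hi >= lo")
                support = (self.lo, self.hi)
            if self.family == "triangular":
                if self.mode is None or not self.lo <= self.mode <= self.hi:
                    raise ValueError(f"{self.name}: mode must lie in [lo, hi]")
        amin, amax = _ADMISSIBLE[self.name]
        if support[0] < amin or support[1] > amax:
            raise ValueError(
                f"{self.name}: support {support} outside admissible range ({amin}, {amax})"
            )

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF; samples are a deterministic transform of uniforms."""
        u = np.asarray(u, dtype=float)
        if self.family == "point":
            return np.full_like(u, self.lo)
        if self.family == "uniform":
            return self.lo + u * (self.hi - self.lo)
        if self.family == "triangular":
            lo, hi, c = self.lo, self.hi, self.mode
            fc = (c - lo) / (hi - lo) if hi > lo else 0.0
            left = lo + np.sqrt(u * (hi - lo) * (c - lo))
            right = hi - np.sqrt((1.0 - u) * (hi - lo) * (hi - c))
            return np.where(u < fc, left, right)
        edges = np.asarray(self.bin_edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        cdf = np.concatenate([[0.0], np.cumsum(w) / w.sum()])
        i = np.clip(np.searchsorted(cdf, u, side="right") - 1, 0, len(w) - 1)
        width = cdf[i + 1] - cdf[i]
        frac = np.where(width > 0, (u - cdf[i]) / np.where(width > 0, width, 1.0), 0.0)
        return edges[i] + frac * (edges[i + 1] - edges[i])


@dataclass(frozen=True)
class ReliabilityResult:
    """Per-draw reliability function and the failure-probability estimate.

    ``rf`` and ``s_re`` have one entry per draw; overcritical (unsolvable)
    draws carry NaN and are excluded from the probability estimate but
    reported in ``n_unsolvable``.
    """

    rf: np.ndarray
    s_re: np.ndarray
    p_fail: float
    ci: tuple[float, float]
    n_draws: int
    n_solvable: int
    n_unsolvable: int
    hist: tuple[np.ndarray, np.ndarray, np.ndarray] | None
    hist_var: str | None


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, name-keyed stream so variables can be shifted alone."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, zlib.crc32(name.encode())])))


def sample_inputs(
    distributions: list[InputDistribution], n_draws: int, seed: int
) -> pd.DataFrame:
    """Reproducible draw table; one column per distribution."""
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    names = [d.name for d in distributions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable in distribution list")
    cols = {}
    for dist in distributions:
        u = _stream(seed, dist.name).random(n_draws)
        cols[dist.name] = dist.ppf(u)
    return pd.DataFrame(cols)


def _case_arrays(draws: pd.DataFrame, template: CaseParams) -> dict[str, np.ndarray]:
    """Template parameters broadcast to per-draw arrays, draw columns override."""
    n = len(draws)
    d_default = template.section.d if template.section.kind == CANNULATED else 0.0
    defaults = {
        "m": template.m,
        "k_m": template.k_m,
        "k_dyn": template.k_dyn,
        "n": template.n,
        "alpha": template.alpha_deg,
        "k": template.k,
        "E": template.E,
        "Re": template.Re,
        "D": template.section.D,
        "d": d_default,
        "L": template.L,
        "L1": template.L1,
        "L2": template.L2,
    }
    out = {}
    for name, default in defaults.items():
        if name in draws.columns:
            out[name] = draws[name].to_numpy(dtype=float)
        else:
            out[name] = np.full(n, float(default))
    return out


def _mechanics(arr: dict[str, np.ndarray]):
    """Vectorized forces, section properties and model arrays."""
    F_m = arr["m"] * arr["k_m"] * arr["k_dyn"] * G
    F = F_m / arr["n"]
    alpha = np.radians(arr["alpha"])
    F1 = F * np.cos(alpha)
    F2 = F * np.sin(alpha)
    N = -F2
    A, J, W_o = annulus_properties(arr["D"], arr["d"])
    EJ = arr["E"] * J
    return F1, N, A, W_o, EJ


def reliability(
    draws: pd.DataFrame,
    template: CaseParams,
    n_samples_per_segment: int = 301,
    refine: bool = False,
    hist_var: str | None = None,
    hist_bins: int = 30,
    max_unsolvable_frac: float = 0.01,
) -> ReliabilityResult:
    """Reliability function RF = Re - |sigma_MAX| over all draws.

    Draws sharing identical mechanical inputs (everything except Re) are
    solved once.  ``refine=True`` routes every unique mechanical draw
    through the exact scalar pipeline (:func:`osteobeam.pipeline.analyze`
    with golden-section extremum refinement) so degenerate distributions
    reproduce the deterministic result bitwise; the default batch path
    uses dense-grid extrema only.
    """
    n_draws = len(draws)
    arr = _case_arrays(draws, template)
    F1, N, A, W_o, EJ = _mechanics(arr)

    solvable = N * N < 4.0 * EJ * arr["k"]
    n_unsolvable = int(np.sum(~solvable))
    if n_unsolvable > max_unsolvable_frac * n_draws:
        raise UnsolvableDrawsError(
            f"{n_unsolvable}/{n_draws} draws are overcritical (N² >= 4·EJ·k); "
            f"tolerated fraction is {max_unsolvable_frac:.2%}. "
            "Check the axial-force and stiffness supports."
        )

    mech_cols = [arr[v] for v in ("m", "k_m", "k_dyn", "n", "alpha", "k", "E", "D", "d", "L", "L1", "L2")]
    mech = np.column_stack(mech_cols)[solvable]
    uniq, inverse = np.unique(mech, axis=0, return_inverse=True)

    if refine:
        u_sigma = np.empty(len(uniq))
        for i, row in enumerate(uniq):
            (m, k_m, k_dyn, ncoef, alpha, k, E, D, d, L, L1, L2) = row
            sec = (
                CrossSection(kind=CANNULATED, D=D, d=d)
                if template.section.kind == CANNULATED
                else CrossSection(kind="full", D=D)
            )
            params = dataclasses.replace(
                template,
                m=m,
                k_m=k_m,
                k_dyn=k_dyn,
                n=ncoef,
                alpha_deg=alpha,
                k=k,
                E=E,
                section=sec,
                L=L,
                L1=L1,
                L2=L2,
            )
            res = analyze(params, n_samples_per_segment=n_samples_per_segment)
            u_sigma[i] = res.stresses.sigma_MAX_abs
        sigma_abs = u_sigma[inverse]
    else:
        u_sigma = np.empty(len(uniq))
        for lo in range(0, len(uniq), _BATCH_CHUNK):
            sl = slice(lo, min(lo + _BATCH_CHUNK, len(uniq)))
            (m, k_m, k_dyn, ncoef, alpha, k, E, D, d, L, L1, L2) = uniq[sl].T
            F_m = m * k_m * k_dyn * G
            F = F_m / ncoef
            al = np.radians(alpha)
            f1 = F * np.cos(al)
            f2 = F * np.sin(al)
            a_, j_, w_ = annulus_properties(D, d)
            ej = E * j_
            _, Mmax, _ = batch_extremes(
                ej, -f2, k, L1, L2, L, f1, n_samples_per_segment=n_samples_per_segment
            )
            s1 = -f2 / a_ - Mmax / w_
            s2 = -f2 / a_ + Mmax / w_
            u_sigma[sl] = np.maximum(np.abs(s1), np.abs(s2))
        sigma_abs = u_sigma[inverse]

    re_arr = arr["Re"][solvable]
    rf = np.full(n_draws, np.nan)
    s_re = np.full(n_draws, np.nan)
    rf[solvable] = re_arr - sigma_abs
    s_re[solvable] = re_arr / sigma_abs

    n_solvable = int(np.sum(solvable))
    n_fail = int(np.sum(rf[solvable] < 0.0))
    p = n_fail / n_solvable
    lo_ci, hi_ci = proportion_confint(n_fail, n_solvable, alpha=0.05, method="wilson")

    hist = None
    if hist_var is None:
        varying = [c for c in draws.columns if np.ptp(draws[c].to_numpy()) > 0]
        hist_var = varying[0] if varying else (draws.columns[0] if len(draws.columns) else None)
    if hist_var is not None and hist_var in draws.columns:
        counts, xe, ye = np.histogram2d(
            draws[hist_var].to_numpy()[solvable], rf[solvable], bins=hist_bins
        )
        hist = (counts, xe, ye)

    return ReliabilityResult(
        rf=rf,
        s_re=s_re,
        p_fail=p,
        ci=(float(lo_ci), float(hi_ci)),
        n_draws=n_draws,
        n_solvable=n_solvable,
        n_unsolvable=n_unsolvable,
        hist=hist,
        hist_var=hist_var,
    )
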