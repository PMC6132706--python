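"""Three-segment beam on an elastic (Winkler) foundation, 2nd-order theory.

The deflection of each segment obeys

    EJ_ZT * v'''' - N * v'' + k * v = 0

with a constant (signed) axial force ``N`` (compression negative) and
foundation stiffness ``k`` [N/m²].  Transverse point loads ``+F1`` at
``L1`` and ``-F1`` at ``L2`` enter through shear-jump conditions; both
beam ends are free (zero moment and shear).  In the sub-critical regime
``N² < 4·EJ·k`` the characteristic roots are ``±omega_I ± i·omega_R`` and
each segment's solution is spanned by

    e^{+omega_I x} cos(omega_R x),  e^{+omega_I x} sin(omega_R x),
    e^{-omega_I x} cos(omega_R x),  e^{-omega_I x} sin(omega_R x).

Twelve constants are fixed by twelve linear boundary/continuity
conditions.  For conditioning, each segment's growing exponential is
referenced to the segment's right end and the decaying one to its left
end (``recenter=True``); this is an exact reparametrization, asserted
equivalent to the plain global basis on short beams.

Sign conventions (shared with :mod:`osteobeam.fdiff` so that comparisons
are convention-free): ``v`` positive in the direction of the load at
``L1``; ``M_o = -EJ·v''``; ``T = -EJ·v''' + N·v'`` (2nd-order shear).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "CharacteristicRoots",
    "ScrewBeamModel",
    "SegmentConstants",
    "Extremum",
    "FieldSolution",
    "characteristic_roots",
    "assemble_system",
    "solve_constants",
    "boundary_residuals",
    "evaluate_fields",
    "fields_at",
    "OvercriticalAxialForceError",
    "IllConditionedSystemError",
    "SingularSystemError",
]

#: condition-number ceiling for the (row-equilibrated) 12x12 block
COND_LIMIT = 1e12


class OvercriticalAxialForceError(ValueError):
    """|N| at or beyond the oscillatory-root limit 2*sqrt(EJ*k)."""


class IllConditionedSystemError(RuntimeError):
    """Assembled block is numerically unusable; re-scale or re-center."""


class SingularSystemError(RuntimeError):
    """The 12x12 block is singular to working precision."""


@dataclass(frozen=True)
class CharacteristicRoots:
    """Oscillatory (omega_R) and decay (omega_I) wavenumbers [1/m]."""

    omega_R: float
    omega_I: float


def characteristic_roots(E: float, J_ZT: float, N: float, k: float) -> CharacteristicRoots:
    """Roots ``±omega_I ± i·omega_R`` of ``EJ·lam⁴ − N·lam² + k = 0``.

    omega_I = sqrt((sqrt(k/EJ) + N/(2EJ))/2),
    omega_R = sqrt((sqrt(k/EJ) − N/(2EJ))/2).

    For ``N = 0`` both collapse to the classical Winkler wavenumber
    ``(k/(4·EJ))^{1/4}``.
    """
    if not (E > 0 and J_ZT > 0 and k > 0):
        raise ValueError(f"E, J_ZT, k must be positive (E={E}, J_ZT={J_ZT}, k={k})")
    EJ = E * J_ZT
    if N * N >= 4.0 * EJ * k:
        raise OvercriticalAxialForceError(
            f"overcritical axial force: N²={N * N:.6g} >= 4·EJ·k={4 * EJ * k:.6g}; "
            "the real-root regime is not implemented"
        )
    S = math.sqrt(k / EJ)
    u = N / (2.0 * EJ)
    return CharacteristicRoots(omega_R=math.sqrt((S - u) / 2.0), omega_I=math.sqrt((S + u) / 2.0))


@dataclass(frozen=True)
class ScrewBeamModel:
    """Boundary-value problem definition (all SI).

    L
        beam length [m]; x = 0 at the screw-head end, x = L at the tip
    L1, L2
        transverse force-transfer abscissae, 0 < L1 < L2 < L; ``+F1``
        acts at L1 and ``-F1`` at L2
    k
        foundation stiffness per unit length of beam [N/m²]
    E, J_ZT
        Young's modulus [Pa] and second moment of area [m⁴]
    F1
        transverse load magnitude [N]
    N
        axial force [N], signed, compression negative; constant along x
    """

    L: float
    L1: float
    L2: float
    k: float
    E: float
    J_ZT: float
    F1: float
    N: float

    def __post_init__(self) -> None:
        if not 0.0 < self.L1 < self.L2 < self.L:
            raise ValueError(
                f"require 0 < L1 < L2 < L, got L1={self.L1}, L2={self.L2}, L={self.L}"
            )
        if not self.k > 0:
            raise ValueError(f"k must be positive, got k={self.k}")
        if not (self.E > 0 and self.J_ZT > 0):
            raise ValueError(f"E and J_ZT must be positive (E={self.E}, J_ZT={self.J_ZT})")
        # raises OvercriticalAxialForceError if outside the oscillatory regime
        characteristic_roots(self.E, self.J_ZT, self.N, self.k)

    @property
    def EJ(self) -> float:
        return self.E * self.J_ZT

    def roots(self) -> CharacteristicRoots:
        return characteristic_roots(self.E, self.J_ZT, self.N, self.k)


@dataclass(frozen=True)
class SegmentConstants:
    """Twelve integration constants, row i = segment i, cols = basis 1..4."""

    A: np.ndarray  # shape (3, 4)
    roots: CharacteristicRoots
    recentered: bool


@dataclass(frozen=True)
class Extremum:
    """Signed field value at the location of maximal magnitude."""

    value: float
    x: float


# ----------------------------------------------------------------------
# basis evaluation (batch-capable: all parameter arguments broadcast)
# ----------------------------------------------------------------------

def _segment_bounds(L1, L2, L):
    return ((0.0 * L1, L1), (L1, L2), (L2, L))


def _basis_cols(wI, wR, x, order, ref_p, ref_m):
    """Columns (phi1..phi4) of the order-th derivative of the basis at x.

    ref_p / ref_m re-center the growing / decaying exponential; passing
    zeros yields the plain global basis.
    """
    lam_p = wI + 1j * wR
    lam_m = -wI + 1j * wR
    zp = lam_p**order * np.exp(lam_p * x - wI * ref_p)
    zm = lam_m**order * np.exp(lam_m * x + wI * ref_m)
    return zp.real, zp.imag, zm.real, zm.imag


def _batch_assemble(wI, wR, L1, L2, L, F1_over_EJ, N_over_EJ, recenter=True):
    """Assemble the 12x12 blocks and right-hand sides for stacked models.

    All inputs are broadcast-compatible 1-D arrays of length n; returns
    (M, B) with shapes (n, 12, 12) and (n, 12).  Moment rows are written
    as ``v'' = 0`` / continuity of ``v''`` and shear rows as
    ``v''' − (N/EJ)·v'`` (i.e. ``−T/EJ``), so the right-hand side holds
    ``∓F1/EJ`` at the two jump rows.
    """
    wI, wR, L1, L2, L, F1_over_EJ, N_over_EJ = np.broadcast_arrays(
        wI, wR, L1, L2, L, F1_over_EJ, N_over_EJ
    )
    n = wI.shape[0]
    M = np.zeros((n, 12, 12))
    B = np.zeros((n, 12))
    bounds = _segment_bounds(L1, L2, L)

    def cols(seg, x, order):
        xl, xr = bounds[seg]
        if recenter:
            ref_p, ref_m = xr, xl
        else:
            ref_p = ref_m = np.zeros_like(xr)
        return _basis_cols(wI, wR, x, order, ref_p, ref_m)

    def put(row, seg, vals, sign=1.0):
        for j, v in enumerate(vals):
            M[:, row, 4 * seg + j] += sign * v

    def shear_cols(seg, x):
        c3 = cols(seg, x, 3)
        c1 = cols(seg, x, 1)
        return tuple(a - N_over_EJ * b for a, b in zip(c3, c1))

    zero = np.zeros_like(L)
    # free end at x = 0: M_o = 0 (v''), T = 0 (v''' - (N/EJ) v')
    put(0, 0, cols(0, zero, 2))
    put(1, 0, shear_cols(0, zero))
    # continuity at L1 (v, v', v'') and shear jump +F1
    for r, order in ((2, 0), (3, 1), (4, 2)):
        put(r, 0, cols(0, L1, order))
        put(r, 1, cols(1, L1, order), sign=-1.0)
    put(5, 0, shear_cols(0, L1))
    put(5, 1, shear_cols(1, L1), sign=-1.0)
    B[:, 5] = -F1_over_EJ  # T1 - T2 = +F1  with  T = -EJ*(v''' - (N/EJ) v')
    # continuity at L2 and shear jump -F1
    for r, order in ((6, 0), (7, 1), (8, 2)):
        put(r, 1, cols(1, L2, order))
        put(r, 2, cols(2, L2, order), sign=-1.0)
    put(9, 1, shear_cols(1, L2))
    put(9, 2, shear_cols(2, L2), sign=-1.0)
    B[:, 9] = F1_over_EJ
    # free end at x = L
    put(10, 2, cols(2, L, 2))
    put(11, 2, shear_cols(2, L))
    return M, B


def _equilibrate(M, B):
    scale = np.max(np.abs(M), axis=-1, keepdims=True)
    if np.any(scale == 0.0):
        raise SingularSystemError("assembled block has an identically zero row")
    return M / scale, B / scale[..., 0]


def assemble_system(model: ScrewBeamModel, recenter: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """The raw (unscaled) 12x12 coefficient block and 12-vector RHS.

    Raises :class:`IllConditionedSystemError` if the row-equilibrated
    block has a condition estimate above 1e12 (suggesting re-centering /
    re-scaling).
    """
    r = model.roots()
    M, B = _batch_assemble(
        np.array([r.omega_I]),
        np.array([r.omega_R]),
        np.array([model.L1]),
        np.array([model.L2]),
        np.array([model.L]),
        np.array([model.F1 / model.EJ]),
        np.array([model.N / model.EJ]),
        recenter=recenter,
    )
    Ms, _ = _equilibrate(M, B)
    cond = np.linalg.cond(Ms[0])
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise IllConditionedSystemError(
            f"condition estimate {cond:.3g} exceeds {COND_LIMIT:.0e}; "
            "re-scale the problem or use the re-centered basis (recenter=True)"
        )
    return M[0], B[0]


def solve_constants(model: ScrewBeamModel, recenter: bool = True) -> SegmentConstants:
    """Solve for the twelve integration constants and verify the BCs."""
    M, B = assemble_system(model, recenter=recenter)
    Ms, Bs = _equilibrate(M, B)
    try:
        A = np.linalg.solve(Ms, Bs)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(Ms)
        raise SingularSystemError(f"singular 12x12 block (condition estimate {cond:.3g})") from exc
    constants = SegmentConstants(A=A.reshape(3, 4), roots=model.roots(), recentered=recenter)
    res = boundary_residuals(model, constants)
    if model.F1 != 0.0 and np.max(np.abs(res)) > 1e-8:
        raise SingularSystemError(
            f"boundary-condition residual {np.max(np.abs(res)):.3g} exceeds 1e-8 of the load"
        )
    return constants


# ----------------------------------------------------------------------
# field evaluation
# ----------------------------------------------------------------------

def _segment_refs(model: ScrewBeamModel, constants: SegmentConstants, seg: int):
    bounds = ((0.0, model.L1), (model.L1, model.L2), (model.L2, model.L))
    xl, xr = bounds[seg]
    if constants.recentered:
        return xr, xl
    return 0.0, 0.0


def _segment_derivative(model, constants, seg, x, order):
    """order-th derivative of v on segment ``seg`` at abscissae ``x``."""
    r = constants.roots
    ref_p, ref_m = _segment_refs(model, constants, seg)
    c = _basis_cols(r.omega_I, r.omega_R, np.asarray(x, dtype=float), order, ref_p, ref_m)
    a = constants.A[seg]
    return a[0] * c[0] + a[1] * c[1] + a[2] * c[2] + a[3] * c[3]


def _segment_fields(model, constants, seg, x):
    """(v, slope, M_o, T) on one segment at abscissae x."""
    v = _segment_derivative(model, constants, seg, x, 0)
    dv = _segment_derivative(model, constants, seg, x, 1)
    d2 = _segment_derivative(model, constants, seg, x, 2)
    d3 = _segment_derivative(model, constants, seg, x, 3)
    M_o = -model.EJ * d2
    T = -model.EJ * d3 + model.N * dv
    return v, dv, M_o, T


def _segment_of(model: ScrewBeamModel, x: np.ndarray) -> np.ndarray:
    """Segment index per abscissa; interior boundaries belong to the right segment."""
    seg = np.searchsorted([model.L1, model.L2], x, side="right")
    return np.where(np.asarray(x) >= model.L, 2, seg)


def fields_at(model: ScrewBeamModel, constants: SegmentConstants, x) -> dict[str, np.ndarray]:
    """Evaluate all fields at arbitrary abscissae in [0, L].

    At L1/L2 the right segment's one-sided values are returned (shear is
    discontinuous there).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    seg = _segment_of(model, x)
    v = np.empty_like(x)
    dv = np.empty_like(x)
    M_o = np.empty_like(x)
    T = np.empty_like(x)
    for s in range(3):
        m = seg == s
        if np.any(m):
            v[m], dv[m], M_o[m], T[m] = _segment_fields(model, constants, s, x[m])
    return {"x": x, "v": v, "slope": dv, "M_o": M_o, "T": T, "q_R": model.k * v}


def _refine_absmax(f, xl, xr, xs, ys) -> Extremum:
    """Golden-section refinement of max |f| seeded from dense samples."""
    i = int(np.argmax(np.abs(ys)))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, len(xs) - 1)]
    best_x, best_y = xs[i], ys[i]
    if hi > lo:
        res = minimize_scalar(
            lambda x: -abs(f(x)), bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
        )
        y = f(res.x)
        if abs(y) >= abs(best_y):
            best_x, best_y = float(res.x), float(y)
    return Extremum(value=float(best_y), x=float(best_x))


@dataclass(frozen=True)
class FieldSolution:
    """Sampled deflection/slope/moment/shear fields with located extrema.

    ``x`` is strictly increasing over [0, L]; at the interior boundaries
    the stored row carries the right segment's one-sided value.  The
    one-sided shear limits enter the extremum search explicitly, so
    ``T_max`` reflects the true jump values.
    """

    x: np.ndarray
    v: np.ndarray
    slope: np.ndarray
    M_o: np.ndarray
    T: np.ndarray
    q_R: np.ndarray
    N: float
    v_max: Extremum
    M_o_max: Extremum
    T_max: Extremum
    model: ScrewBeamModel
    constants: SegmentConstants

    def at(self, x) -> dict[str, np.ndarray]:
        return fields_at(self.model, self.constants, x)


def evaluate_fields(
    model: ScrewBeamModel, constants: SegmentConstants, n_samples_per_segment: int = 2001
) -> FieldSolution:
    """Sample all fields and locate the extrema of v, M_o and T.

    Each segment is sampled densely on its closed interval; extrema are
    refined by golden-section search to 1e-10 absolute in x.
    """
    if n_samples_per_segment < 2:
        raise ValueError("n_samples_per_segment must be >= 2")
    bounds = ((0.0, model.L1), (model.L1, model.L2), (model.L2, model.L))
    per_seg = []
    for s, (xl, xr) in enumerate(bounds):
        xs = np.linspace(xl, xr, n_samples_per_segment)
        v, dv, M_o, T = _segment_fields(model, constants, s, xs)
        per_seg.append({"x": xs, "v": v, "slope": dv, "M_o": M_o, "T": T})

    extrema = {}
    for name in ("v", "M_o", "T"):
        cands = []
        for s, tab in enumerate(per_seg):
            def f(x, s=s, name=name):
                v, dv, M_o, T = _segment_fields(model, constants, s, x)
                return {"v": v, "M_o": M_o, "T": T}[name]

            cands.append(_refine_absmax(f, *bounds[s], tab["x"], tab[name]))
        extrema[name] = max(cands, key=lambda e: abs(e.value))

    # strictly increasing concatenation: drop the duplicated left rows so
    # the boundary rows carry the right segment's one-sided values
    def cat(key):
        return np.concatenate([per_seg[0][key][:-1], per_seg[1][key][:-1], per_seg[2][key]])

    x = cat("x")
    v = cat("v")
    return FieldSolution(
        x=x,
        v=v,
        slope=cat("slope"),
        M_o=cat("M_o"),
        T=cat("T"),
        q_R=model.k * v,
        N=model.N,
        v_max=extrema["v"],
        M_o_max=extrema["M_o"],
        T_max=extrema["T"],
        model=model,
        constants=constants,
    )


def boundary_residuals(model: ScrewBeamModel, constants: SegmentConstants) -> np.ndarray:
    """Normalized residuals of the twelve boundary conditions.

    Force-type rows are scaled by F1, moment rows by F1/omega and
    deflection/slope rows by the characteristic Winkler response, so each
    entry reads "fraction of the applied load".  For F1 = 0 the raw
    residuals are returned.
    """
    r = constants.roots
    omega = math.sqrt(r.omega_I**2 + r.omega_R**2)
    F1 = model.F1 if model.F1 != 0.0 else 1.0
    v_ref = F1 * omega / (2.0 * model.k)
    m_ref = F1 / omega

    def at(seg, x):
        return _segment_fields(model, constants, seg, np.array([x]))

    v0, dv0, M0, T0 = at(0, 0.0)
    vL, dvL, ML, TL = at(2, model.L)
    a1 = at(0, model.L1)
    b1 = at(1, model.L1)
    a2 = at(1, model.L2)
    b2 = at(2, model.L2)
    res = np.array(
        [
            M0[0] / m_ref,
            T0[0] / F1,
            (a1[0][0] - b1[0][0]) / v_ref,
            (a1[1][0] - b1[1][0]) / (v_ref * omega),
            (a1[2][0] - b1[2][0]) / m_ref,
            (a1[3][0] - b1[3][0] - model.F1) / F1,
            (a2[0][0] - b2[0][0]) / v_ref,
            (a2[1][0] - b2[1][0]) / (v_ref * omega),
            (a2[2][0] - b2[2][0]) / m_ref,
            (a2[3][0] - b2[3][0] + model.F1) / F1,
            ML[0] / m_ref,
            TL[0] / F1,
        ]
    )
    return res


# ----------------------------------------------------------------------
# batched pipeline core (used by the Monte-Carlo engine)
# ----------------------------------------------------------------------

def batch_extremes(
    EJ: np.ndarray,
    N: np.ndarray,
    k: np.ndarray,
    L1: np.ndarray,
    L2: np.ndarray,
    L: np.ndarray,
    F1: np.ndarray,
    n_samples_per_segment: int = 301,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(max|v|, signed M_o at max|M_o|, max|T|) for stacked sub-critical models.

    Dense-grid extrema only (no golden-section refinement); the caller
    must have screened out overcritical draws (``N² >= 4·EJ·k``).
    """
    EJ, N, k, L1, L2, L, F1 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (EJ, N, k, L1, L2, L, F1))
    )
    S = np.sqrt(k / EJ)
    u = N / (2.0 * EJ)
    if np.any(u * u >= k / EJ):
        raise OvercriticalAxialForceError("batch contains overcritical draws; screen them first")
    wI = np.sqrt((S + u) / 2.0)
    wR = np.sqrt((S - u) / 2.0)
    M, B = _batch_assemble(wI, wR, L1, L2, L, F1 / EJ, N / EJ, recenter=True)
    Ms, Bs = _equilibrate(M, B)
    A = np.linalg.solve(Ms, Bs[..., None])[..., 0]  # (n, 12)

    n = A.shape[0]
    vmax = np.zeros(n)
    Mmax = np.zeros(n)
    Mabs = np.zeros(n)
    Tmax = np.zeros(n)
    xi = np.linspace(0.0, 1.0, n_samples_per_segment)
    bounds = _segment_bounds(L1, L2, L)
    for s, (xl, xr) in enumerate(bounds):
        x = xl[:, None] + xi[None, :] * (xr - xl)[:, None]
        ref_p, ref_m = xr[:, None], xl[:, None]
        a = A[:, 4 * s : 4 * s + 4]

        def deriv(order):
            c = _basis_cols(wI[:, None], wR[:, None], x, order, ref_p, ref_m)
            return (
                a[:, 0:1] * c[0] + a[:, 1:2] * c[1] + a[:, 2:3] * c[2] + a[:, 3:4] * c[3]
            )

        v = deriv(0)
        M_o = -EJ[:, None] * deriv(2)
        T = -EJ[:, None] * deriv(3) + N[:, None] * deriv(1)
        vmax = np.maximum(vmax, np.max(np.abs(v), axis=1))
        seg_Mabs = np.abs(M_o)
        j = np.argmax(seg_Mabs, axis=1)
        take = seg_Mabs[np.arange(n), j] > Mabs
        Mabs = np.where(take, seg_Mabs[np.arange(n), j], Mabs)
        Mmax = np.where(take, M_o[np.arange(n), j], Mmax)
        Tmax = np.maximum(Tmax, np.max(np.abs(T), axis=1))
    return vmax, Mmax, Tmax
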