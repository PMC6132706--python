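"""Central finite-difference oracle for the foundation-beam problem.

Independent of the analytic solver: discretizes

    EJ * v'''' - N * v'' + k * v = q(x)

with 3-point central stencils on the equivalent mixed second-order system

    M_b = -EJ * v''                 (bending moment)
    -M_b'' - N * v'' + k * v = q    (transverse equilibrium)

The mixed form is essential numerically: collocating the raw 4th-order
operator puts EJ/h^4 and k in the same matrix entry, and on fine grids
the foundation term (which carries all the low-mode physics of a
free-free beam) is rounded away in double precision.  In the mixed form
the stencil scales are EJ/h^2 and N/h^2 vs. k, which double handles.

The point loads (+F1 near L1, -F1 near L2) are applied as single-node
forces F1/h at the nearest grid node; free ends are enforced through
ghost nodes carrying M_o = 0 and T = 0.  Sign conventions match
:mod:`osteobeam.solver` (``T = M_b' + N·v' = -EJ·v''' + N·v'``), so
comparisons between the two solvers are convention-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .solver import ScrewBeamModel

__all__ = ["FDSolution", "fd_solve"]


@dataclass(frozen=True)
class FDSolution:
    """Nodal fields from the finite-difference solve.

    ``snap`` records how far each load abscissa moved to its grid node;
    ``load_nodes`` are the node indices carrying the point forces.
    """

    x: np.ndarray
    v: np.ndarray
    slope: np.ndarray
    M_o: np.ndarray
    T: np.ndarray
    q_R: np.ndarray
    h: float
    snap: dict[str, float]
    load_nodes: tuple[int, int]


def fd_solve(model: ScrewBeamModel, M: int = 10001) -> FDSolution:
    """Solve the beam with ``M`` equally spaced nodes (``M >= 101``).

    Unknowns are the nodal deflections and bending moments plus one ghost
    node per field per end; both governing equations are collocated at
    every real node and the four free-end conditions (M_o = T = 0) close
    the system.  A sparse direct solve plus two rounds of mixed-precision
    iterative refinement (extended-precision assembly/residual) keeps the
    result discretization-limited even for extreme stiffness ratios.
    """
    if M < 101:
        raise ValueError(f"node count M must be >= 101, got {M}")
    L, EJ, N, k, F1 = model.L, model.EJ, model.N, model.k, model.F1
    h = L / (M - 1)
    x = np.linspace(0.0, L, M)

    j1 = int(round(model.L1 / h))
    j2 = int(round(model.L2 / h))
    if j1 == j2:
        raise ValueError("grid too coarse: both load abscissae snap to the same node")
    snap = {"L1": j1 * h - model.L1, "L2": j2 * h - model.L2}

    # unknowns: v_{-1}..v_M at 0..M+1, then M_{-1}..M_M at M+2..2M+3
    nv = M + 2
    nunk = 2 * nv

    def iv(j):  # v_j, j in [-1, M]
        return j + 1

    def im(j):  # M_j
        return nv + j + 1

    rows, cols, vals = [], [], []
    rhs = np.zeros(nunk)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    ih2 = 1.0 / h**2
    for i in range(M):
        # moment definition at node i: M_i + EJ*(v_{i-1}-2v_i+v_{i+1})/h² = 0
        r = i
        add(r, im(i), 1.0)
        add(r, iv(i - 1), EJ * ih2)
        add(r, iv(i), -2.0 * EJ * ih2)
        add(r, iv(i + 1), EJ * ih2)
        # equilibrium at node i: -(M'')_i - N*(v'')_i + k*v_i = q_i
        r = M + i
        add(r, im(i - 1), -ih2)
        add(r, im(i), 2.0 * ih2)
        add(r, im(i + 1), -ih2)
        add(r, iv(i - 1), -N * ih2)
        add(r, iv(i), 2.0 * N * ih2)
        add(r, iv(i + 1), -N * ih2)
        add(r, iv(i), k)
    rhs[M + j1] += F1 / h
    rhs[M + j2] -= F1 / h

    # free ends: M_o = 0 and T = M' + N*v' = 0 at both ends
    i2h = 1.0 / (2.0 * h)
    r = 2 * M
    add(r, im(0), 1.0)
    r = 2 * M + 1
    add(r, im(1), i2h)
    add(r, im(-1), -i2h)
    add(r, iv(1), N * i2h)
    add(r, iv(-1), -N * i2h)
    r = 2 * M + 2
    add(r, im(M - 1), 1.0)
    r = 2 * M + 3
    add(r, im(M), i2h)
    add(r, im(M - 2), -i2h)
    add(r, iv(M), N * i2h)
    add(r, iv(M - 2), -N * i2h)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(nunk, nunk))
    try:
        lu = splu(A.tocsc())
        u = lu.solve(rhs)
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise RuntimeError(f"singular band system in fd_solve: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise RuntimeError("singular band system in fd_solve (non-finite solution)")

    A_ld = sp.coo_matrix(
        (np.array(vals, dtype=np.longdouble), (rows, cols)), shape=(nunk, nunk)
    ).tocsr()
    rhs_ld = rhs.astype(np.longdouble)
    u_ld = u.astype(np.longdouble)
    for _ in range(2):
        r = rhs_ld - A_ld @ u_ld
        u_ld = u_ld + lu.solve(np.asarray(r, dtype=float)).astype(np.longdouble)
    u = np.asarray(u_ld, dtype=float)

    v_all = u[:nv]  # v_{-1} .. v_M
    m_all = u[nv:]  # M_{-1} .. M_M
    v = v_all[1 : M + 1]
    M_o = m_all[1 : M + 1]
    slope = (v_all[2 : M + 2] - v_all[0:M]) * i2h
    T = (m_all[2 : M + 2] - m_all[0:M]) * i2h + N * slope
    return FDSolution(
        x=x, v=v, slope=slope, M_o=M_o, T=T, q_R=k * v, h=h, snap=snap, load_nodes=(j1, j2)
    )
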