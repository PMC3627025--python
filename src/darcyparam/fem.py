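"""Trilinear hexahedral finite elements for the multi-compartment Darcy system.

The solved compartment obeys

    -div(K grad p) + (b12 + b23) p = b12 pbar1 + b23 pbar3      in Omega,
    K grad p . n = 0                                            on dOmega,

the strong form of Darcy's law ``w = -K grad p`` with volumetric exchange
terms ``-sum_k beta_ik (p_i - p_k)`` against compartments whose pressures
are imposed from the averaged discrete solution.  ``b`` here is the coupling
coefficient per unit volume (Pa^-1 s^-1): the RVE-averaged beta
(mm^3 Pa^-1 s^-1) divided by the local clipped RVE volume.

Discretisation: uniform hexahedral mesh, trilinear (Q1) elements, full
2x2x2 Gauss quadrature, nodal fields interpolated trilinearly to quadrature
points, sparse direct factorisation.  Dirichlet conditions (used by the
single-compartment face-flow protocol) are eliminated symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["GridMesh", "DarcyProblem", "DarcySolution", "build_grid",
           "assemble", "assemble_components", "solve_darcy",
           "mass_balance_report", "check_symmetric_coupling"]


@dataclass
class GridMesh:
    """Uniform hexahedral mesh over a box: (n+1)^3 nodes, n^3 elements."""

    box: np.ndarray  # (3, 2)
    n: int

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        axes = [np.linspace(self.box[a, 0], self.box[a, 1], self.n + 1) for a in range(3)]
        self.axes = axes
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        self.nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        self.spacing = (self.box[:, 1] - self.box[:, 0]) / self.n

    @property
    def n_nodes(self) -> int:
        return (self.n + 1) ** 3

    @property
    def n_elements(self) -> int:
        return self.n**3

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.n + 1,) * 3

    def node_index(self, i, j, k):
        m = self.n + 1
        return (np.asarray(i) * m + np.asarray(j)) * m + np.asarray(k)

    def element_nodes(self) -> np.ndarray:
        """(n^3, 8) node indices per element, lexicographic corner order."""
        n = self.n
        i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
        i, j, k = i.ravel(), j.ravel(), k.ravel()
        corners = []
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    corners.append(self.node_index(i + di, j + dj, k + dk))
        return np.column_stack(corners)

    def boundary_nodes(self, axis: int, side: int) -> np.ndarray:
        """Node indices of the face ``axis`` at low (0) or high (1) side."""
        m = self.n + 1
        idx = [np.arange(m)] * 3
        idx[axis] = np.array([0 if side == 0 else self.n])
        I, J, K = np.meshgrid(*idx, indexing="ij")
        return self.node_index(I, J, K).ravel()


def build_grid(box, n: int) -> GridMesh:
    """Uniform hexahedral mesh with ``n`` intervals per axis."""
    return GridMesh(np.asarray(box, dtype=float), n)


def _reference_quadrature() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gauss 2x2x2 points: shape values (8,8), ref gradients (8,8,3), weights."""
    g = 1.0 / np.sqrt(3.0)
    qp = np.array(
        [[sx * g, sy * g, sz * g] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    signs = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    N = np.empty((8, 8))
    dN = np.empty((8, 8, 3))
    for q, (x, y, z) in enumerate(qp):
        for a, (sx, sy, sz) in enumerate(signs):
            N[q, a] = (1 + sx * x) * (1 + sy * y) * (1 + sz * z) / 8.0
            dN[q, a] = np.array(
                [
                    sx * (1 + sy * y) * (1 + sz * z),
                    (1 + sx * x) * sy * (1 + sz * z),
                    (1 + sx * x) * (1 + sy * y) * sz,
                ]
            ) / 8.0
    w = np.ones(8)
    return N, dN, w


@dataclass
class DarcyProblem:
    """Single solved compartment with imposed neighbour pressures.

    ``K`` is the (M, 3, 3) nodal permeability; ``beta_vol`` maps imposed
    compartment label -> nodal per-unit-volume coupling (Pa^-1 s^-1);
    ``imposed_pressure`` maps the same labels -> nodal pressures (Pa).
    ``dirichlet`` optionally fixes solved-compartment pressures at nodes
    (node index -> Pa); elsewhere the zero-flux condition is natural.
    """

    K: np.ndarray
    beta_vol: Dict[int, np.ndarray]
    imposed_pressure: Dict[int, np.ndarray]
    dirichlet: Optional[Dict[int, float]] = None

    def validate(self, mesh: GridMesh) -> None:
        M = mesh.n_nodes
        if self.K.shape != (M, 3, 3):
            raise ValueError("K has wrong shape")
        if set(self.beta_vol) != set(self.imposed_pressure):
            raise ValueError("beta_vol and imposed_pressure must cover the same compartments")
        for lab, b in self.beta_vol.items():
            if b.shape != (M,) or self.imposed_pressure[lab].shape != (M,):
                raise ValueError("nodal field has wrong shape")
            if np.any(b < 0):
                raise ValueError(f"beta for compartment {lab} has negative entries")
        if not np.allclose(self.K, np.swapaxes(self.K, 1, 2)):
            raise ValueError("K tensors must be symmetric")


@dataclass
class DarcySolution:
    pressure: np.ndarray  # (M,) Pa
    velocity: np.ndarray  # (n_elements, 3) at element centres
    residual: float
    scale: float = 1.0


def assemble_components(
    problem: DarcyProblem, mesh: GridMesh
) -> Tuple[sp.csr_matrix, sp.csr_matrix, np.ndarray]:
    """Stiffness S, exchange mass matrix Mx and load f (no BC elimination).

    The assembled system is ``(S + Mx) p = f``; splitting S out lets a
    scalar permeability rescale reuse the assembly (``s S + Mx``).
    """
    problem.validate(mesh)
    N, dN, w = _reference_quadrature()
    h = mesh.spacing
    detJ = np.prod(h) / 8.0
    dNp = dN * (2.0 / h)[None, None, :]  # physical gradients, (8q, 8a, 3)
    conn = mesh.element_nodes()  # (E, 8)
    Ke = problem.K[conn]  # (E, 8, 3, 3)
    bsum = np.zeros(mesh.n_nodes)
    load = np.zeros(mesh.n_nodes)
    for lab, b in problem.beta_vol.items():
        bsum += b
        load += b * problem.imposed_pressure[lab]
    be = bsum[conn]  # (E, 8)
    fe = load[conn]
    # stiffness: sum_q w detJ dN_a . Kq . dN_b with Kq = sum_c N_qc K_c
    Kq = np.einsum("qc,ecij->eqij", N, Ke)
    S_el = np.einsum("q,qai,eqij,qbj->eab", w * detJ, dNp, Kq, dNp, optimize=True)
    bq = np.einsum("qc,ec->eq", N, be)
    M_el = np.einsum("q,eq,qa,qb->eab", w * detJ, bq, N, N, optimize=True)
    fq = np.einsum("qc,ec->eq", N, fe)
    f_el = np.einsum("q,eq,qa->ea", w * detJ, fq, N, optimize=True)
    rows = np.repeat(conn, 8, axis=1).ravel()
    cols = np.tile(conn, (1, 8)).ravel()
    M = mesh.n_nodes
    S = sp.csr_matrix((S_el.ravel(), (rows, cols)), shape=(M, M))
    Mx = sp.csr_matrix((M_el.ravel(), (rows, cols)), shape=(M, M))
    f = np.zeros(M)
    np.add.at(f, conn.ravel(), f_el.ravel())
    return S, Mx, f


def assemble(
    problem: DarcyProblem, mesh: GridMesh
) -> Tuple[sp.csr_matrix, np.ndarray, np.ndarray, np.ndarray]:
    """Assembled system after Dirichlet elimination.

    Returns ``(A_ff, rhs_f, free_mask, p_fixed)`` where ``p_fixed`` holds
    Dirichlet values on fixed nodes (0 elsewhere).
    """
    S, Mx, f = assemble_components(problem, mesh)
    A = (S + Mx).tocsr()
    M = mesh.n_nodes
    fixed = np.zeros(M, dtype=bool)
    p_fixed = np.zeros(M)
    if problem.dirichlet:
        for nid, val in problem.dirichlet.items():
            fixed[nid] = True
            p_fixed[nid] = val
    if not problem.dirichlet and all(
        not b.any() for b in problem.beta_vol.values()
    ):
        raise ValueError(
            "pure-Neumann problem with beta identically zero is singular; "
            "impose a Dirichlet pressure or provide exchange coupling"
        )
    free = ~fixed
    A_ff = A[free][:, free].tocsc()
    rhs = f[free] - A[free][:, fixed] @ p_fixed[fixed]
    return A_ff, rhs, free, p_fixed


def solve_darcy(problem: DarcyProblem, mesh: GridMesh) -> DarcySolution:
    """Solve for the compartment pressure; velocity at element centres."""
    A_ff, rhs, free, p = assemble(problem, mesh)
    sol = spla.spsolve(A_ff, rhs)
    p = p.copy()
    p[free] = sol
    res = float(np.linalg.norm(A_ff @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if not np.all(np.isfinite(p)):
        raise RuntimeError("Darcy solve failed: non-finite solution")
    vel = element_velocities(problem.K, p, mesh)
    return DarcySolution(pressure=p, velocity=vel, residual=res)


def element_velocities(K: np.ndarray, p: np.ndarray, mesh: GridMesh) -> np.ndarray:
    """Darcy velocity w = -K grad p at element centres."""
    conn = mesh.element_nodes()
    h = mesh.spacing
    signs = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    # gradient of trilinear basis at the element centre (xi = 0)
    dN0 = signs / 8.0 * (2.0 / h)[None, :]
    grad = np.einsum("ea,ai->ei", p[conn], dN0)
    Kc = K[conn].mean(axis=1)
    return -np.einsum("eij,ej->ei", Kc, grad)


def mass_balance_report(
    solution: DarcySolution, problem: DarcyProblem, mesh: GridMesh
) -> float:
    """Global balance |integral of exchange + boundary outflow|.

    Under zero-Neumann conditions with symmetric non-negative coupling the
    exchange terms must integrate against the constant test function to the
    (signed) total mass exchanged, which the weak form balances to solver
    precision: ``1^T (S p + Mx p - f) = 0`` and ``1^T S p = 0`` exactly.
    For Dirichlet problems the boundary flux through the fixed nodes is the
    corresponding residual contribution and is included.
    """
    S, Mx, f = assemble_components(problem, mesh)
    r = S @ solution.pressure + Mx @ solution.pressure - f
    # on Dirichlet nodes r equals the discrete boundary flux (reaction)
    return float(abs(r.sum()))


def check_symmetric_coupling(betas: Mapping[Tuple[int, int], np.ndarray]) -> None:
    """Verify beta_ik == beta_ki wherever both orientations are supplied.

    Mass exchanged from i to k must re-enter k from i with the same
    coefficient, otherwise the multi-compartment system creates or destroys
    fluid; an asymmetric pair raises ``ValueError``.
    """
    for (i, k), b in betas.items():
        rev = betas.get((k, i))
        if rev is not None and not np.array_equal(
            np.asarray(b, float), np.asarray(rev, float)
        ):
            raise ValueError(f"beta[{i},{k}] != beta[{k},{i}]: coupling is asymmetric")
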