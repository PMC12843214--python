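"""Plane-strain finite-element solver on constant-strain triangles.

Linear path: direct sparse factorization (deterministic ordering, reproducible
bitwise).  Nonlinear path: total-Lagrangian Newton iteration with the Ogden
PDL, incremental loading, and an honest convergence flag.  Out-of-plane
thickness is 1 mm, so forces are N per unit thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh, PDL
from .materials import MaterialCard, plane_strain_matrix, _ogden_stress_batch

__all__ = ["LoadCase", "Solution", "solve_linear", "solve_newton",
           "displacement_at", "structured_rectangle"]


class SolverError(RuntimeError):
    pass


@dataclass
class LoadCase:
    """Point loads (N per unit thickness), Dirichlet constraints (mm) and a
    pseudo-time load factor in [0, 1]."""

    point_loads: list = field(default_factory=list)   # (node, (fx, fy))
    dirichlet: list = field(default_factory=list)     # (node, comps, values)
    load_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.load_factor <= 1.0:
            raise SolverError(f"load_factor must be in [0, 1], got {self.load_factor!r}")
        n_con = sum(len(comps) for _, comps, _ in self.dirichlet)
        if n_con < 3:
            raise SolverError(
                f"at least 3 constrained degrees of freedom are required to "
                f"remove rigid-body modes (got {n_con})")

    def external_force(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(2 * n_nodes)
        for node, fv in self.point_loads:
            f[2 * node] += fv[0]
            f[2 * node + 1] += fv[1]
        return f * self.load_factor

    def constrained_dofs(self, n_nodes: int):
        dofs, vals = [], []
        for node, comps, values in self.dirichlet:
            for c, v in zip(comps, values):
                dofs.append(2 * node + c)
                vals.append(v * self.load_factor if v else 0.0)
        dofs = np.asarray(dofs, dtype=np.int64)
        if len(np.unique(dofs)) != len(dofs):
            raise SolverError("duplicate Dirichlet constraint on a dof")
        if np.any(dofs < 0) or np.any(dofs >= 2 * n_nodes):
            raise SolverError("Dirichlet node index out of range")
        return dofs, np.asarray(vals, dtype=float)


@dataclass
class Solution:
    """Nodal displacements (mm), element Cauchy stresses (MPa), diagnostics."""

    node_displacements: np.ndarray        # (N, 2) mm
    element_stress: np.ndarray            # (M, 2, 2) MPa
    converged: bool
    iterations: int
    reactions: np.ndarray | None = None   # (N, 2) N, nonzero at Dirichlet nodes
    external_force: np.ndarray | None = None
    residual_norm: float = 0.0

    def strain_energy(self) -> float:
        """External work 0.5 f.u — equals strain energy on the linear path."""
        if self.external_force is None:
            raise SolverError("solution carries no external force record")
        return 0.5 * float(self.external_force @ self.node_displacements.ravel())


# ---------------------------------------------------------------------------
# Element kinematics
# ---------------------------------------------------------------------------

def _element_geometry(mesh: Mesh):
    """Per-element CST shape-function data: areas (M,), B matrices (M, 3, 6)."""
    p = mesh.nodes[mesh.elements]          # (M, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    if np.any(area <= 0):
        bad = int(np.argmax(area <= 0))
        raise SolverError(f"inverted or degenerate element {bad} (area <= 0)")
    M = len(area)
    B = np.zeros((M, 3, 6))
    inv2A = 1.0 / (2.0 * area)
    for a in range(3):
        B[:, 0, 2 * a] = b[:, a] * inv2A
        B[:, 1, 2 * a + 1] = c[:, a] * inv2A
        B[:, 2, 2 * a] = c[:, a] * inv2A
        B[:, 2, 2 * a + 1] = b[:, a] * inv2A
    return area, B


def _element_D(mesh: Mesh, mats: MaterialCard) -> np.ndarray:
    mats.require_regions(mesh.element_region)
    D = np.empty((mesh.n_elements, 3, 3))
    for label in np.unique(mesh.element_region):
        idx = mesh.element_region == label
        D[idx] = plane_strain_matrix(mats.materials[label])
    return D


def _dof_matrix(elements: np.ndarray) -> np.ndarray:
    """(M, 6) global dof indices per element."""
    M = len(elements)
    dof = np.empty((M, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * elements
    dof[:, 1::2] = 2 * elements + 1
    return dof


def _assemble(Ke: np.ndarray, dof: np.ndarray, ndof: int) -> sp.csr_matrix:
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof))
    return K.tocsr()


def _stiffness(mesh: Mesh, mats: MaterialCard, mask=None):
    """Assembled stiffness for (a subset of) elements."""
    area, B = _element_geometry(mesh)
    D = _element_D(mesh, mats)
    if mask is not None:
        area, B, D = area[mask], B[mask], D[mask]
        dof = _dof_matrix(mesh.elements[mask])
    else:
        dof = _dof_matrix(mesh.elements)
    Ke = np.einsum("e,eki,ekl,elj->eij", area, B, D, B, optimize=True)
    return _assemble(Ke, dof, 2 * mesh.n_nodes)


def _solve_constrained(K: sp.csr_matrix, f: np.ndarray, con_dofs, con_vals):
    ndof = K.shape[0]
    free = np.setdiff1d(np.arange(ndof), con_dofs)
    u = np.zeros(ndof)
    u[con_dofs] = con_vals
    rhs = f[free] - K[free][:, con_dofs] @ con_vals
    Kff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff, permc_spec="NATURAL", options={"SymmetricMode": True})
        uf = lu.solve(rhs)
    except RuntimeError as exc:
        raise SolverError(
            "singular system: insufficient constraints leave rigid-body "
            f"modes ({exc})") from exc
    if not np.all(np.isfinite(uf)):
        raise SolverError("singular system: non-finite solution "
                          "(insufficient constraints?)")
    u[free] = uf
    return u, free


def _stresses_linear(mesh, mats, u):
    area, B = _element_geometry(mesh)
    D = _element_D(mesh, mats)
    dof = _dof_matrix(mesh.elements)
    ue = u[dof]                                   # (M, 6)
    sv = np.einsum("ekl,elj,ej->ek", D, B, ue)    # (M, 3) voigt
    sig = np.empty((mesh.n_elements, 2, 2))
    sig[:, 0, 0] = sv[:, 0]
    sig[:, 1, 1] = sv[:, 1]
    sig[:, 0, 1] = sig[:, 1, 0] = sv[:, 2]
    return sig


def solve_linear(mesh: Mesh, mats: MaterialCard, load: LoadCase) -> Solution:
    """Solve the linear plane-strain problem and recover element stresses."""
    K = _stiffness(mesh, mats)
    f = load.external_force(mesh.n_nodes)
    con_dofs, con_vals = load.constrained_dofs(mesh.n_nodes)
    u, free = _solve_constrained(K, f, con_dofs, con_vals)
    r = K @ u - f
    res = np.linalg.norm(r[free]) / max(np.linalg.norm(f), 1e-30)
    reactions = np.zeros_like(f)
    reactions[con_dofs] = r[con_dofs]
    return Solution(
        node_displacements=u.reshape(-1, 2),
        element_stress=_stresses_linear(mesh, mats, u),
        converged=True, iterations=1,
        reactions=reactions.reshape(-1, 2),
        external_force=f, residual_norm=float(res))


# ---------------------------------------------------------------------------
# Nonlinear (Ogden PDL) path
# ---------------------------------------------------------------------------

def _pdl_kinematics(mesh: Mesh, pdl_idx: np.ndarray):
    """Reference shape gradients G (Mp, 3, 2) and areas for PDL elements."""
    p = mesh.nodes[mesh.elements[pdl_idx]]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    G = np.stack([b, c], axis=2) / (2.0 * area)[:, None, None]  # dN_a/dX
    return area, G


def _pdl_internal_force(ogden, area, G, ue):
    """Internal nodal forces (Mp, 6) for PDL elements at element dofs ue."""
    # displacement gradient H_ij = sum_a u_a_i G_a_j
    ua = ue.reshape(-1, 3, 2)
    H = np.einsum("eai,eaj->eij", ua, G)
    F = H.copy()
    F[:, 0, 0] += 1.0
    F[:, 1, 1] += 1.0
    sig = _ogden_stress_batch(ogden, F)
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    Finv = np.empty_like(F)
    Finv[:, 0, 0] = F[:, 1, 1] / J
    Finv[:, 1, 1] = F[:, 0, 0] / J
    Finv[:, 0, 1] = -F[:, 0, 1] / J
    Finv[:, 1, 0] = -F[:, 1, 0] / J
    P = J[:, None, None] * np.einsum("eik,ejk->eij", sig, Finv)  # sig F^-T
    fa = area[:, None, None] * np.einsum("eij,eaj->eai", P, G)
    return fa.reshape(-1, 6)


def solve_newton(mesh: Mesh, mats: MaterialCard, load: LoadCase,
                 steps: int = 5, max_iter: int = 30, tol: float = 1e-8,
                 fd_eps: float = 1e-7) -> Solution:
    """Incremental-load Newton solution with the Ogden PDL.

    The PDL elements follow the hyperelastic law (total-Lagrangian CST, the
    consistent tangent approximated by forward differences of the element
    internal force); all other regions stay linear.  Returns ``converged``
    False with diagnostics if the residual does not fall below ``tol``
    relative within ``max_iter`` total Newton iterations — never silently.
    """
    if mats.pdl_model != "ogden":
        raise SolverError("solve_newton requires pdl_model='ogden'")
    if steps < 1:
        raise SolverError("steps must be >= 1")
    pdl_mask = mesh.element_region == PDL
    lin_mask = ~pdl_mask
    K_lin = _stiffness(mesh, mats, mask=lin_mask)
    area_p, G_p = _pdl_kinematics(mesh, np.flatnonzero(pdl_mask))
    dof_p = _dof_matrix(mesh.elements[pdl_mask])
    ndof = 2 * mesh.n_nodes

    f_full = load.external_force(mesh.n_nodes)
    con_dofs, con_vals = load.constrained_dofs(mesh.n_nodes)
    free = np.setdiff1d(np.arange(ndof), con_dofs)

    def f_int(u):
        fi = K_lin @ u
        fe = _pdl_internal_force(mats.pdl_ogden, area_p, G_p, u[dof_p])
        np.add.at(fi, dof_p.ravel(), fe.ravel())
        return fi

    def tangent(u):
        ue = u[dof_p]
        f0 = _pdl_internal_force(mats.pdl_ogden, area_p, G_p, ue)
        Ke = np.empty((len(area_p), 6, 6))
        for k in range(6):
            up = ue.copy()
            up[:, k] += fd_eps
            Ke[:, :, k] = (_pdl_internal_force(mats.pdl_ogden, area_p, G_p, up)
                           - f0) / fd_eps
        Ke = 0.5 * (Ke + np.transpose(Ke, (0, 2, 1)))
        return K_lin + _assemble(Ke, dof_p, ndof)

    u = np.zeros(ndof)
    total_iter = 0
    converged = True
    res = 0.0
    fnorm_full = max(np.linalg.norm(f_full), 1e-30)
    for s in range(1, steps + 1):
        frac = s / steps
        f_t = f_full * frac
        u[con_dofs] = con_vals * frac
        for _ in range(max_iter):
            r = f_t - f_int(u)
            res = np.linalg.norm(r[free]) / fnorm_full
            if res < tol:
                break
            if total_iter >= max_iter:
                break
            Kt = tangent(u)
            du = np.zeros(ndof)
            Kff = Kt[free][:, free].tocsc()
            lu = spla.splu(Kff, permc_spec="NATURAL")
            du[free] = lu.solve(r[free])
            if not np.all(np.isfinite(du)):
                converged = False
                break
            u += du
            total_iter += 1
        else:
            converged = False
        if res >= tol:
            converged = False
        if not converged:
            break

    # stresses: linear regions from the linear law, PDL from the Ogden law
    sig = _stresses_linear(mesh, mats, u)
    if pdl_mask.any():
        ua = u[dof_p].reshape(-1, 3, 2)
        H = np.einsum("eai,eaj->eij", ua, G_p)
        F = H.copy()
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        sig[pdl_mask] = _ogden_stress_batch(mats.pdl_ogden, F)

    r = f_full - f_int(u)
    reactions = np.zeros(ndof)
    reactions[con_dofs] = -r[con_dofs]
    return Solution(
        node_displacements=u.reshape(-1, 2),
        element_stress=sig,
        converged=converged, iterations=total_iter,
        reactions=reactions.reshape(-1, 2),
        external_force=f_full, residual_norm=float(res))


def displacement_at(sol: Solution, node: int) -> np.ndarray:
    """Displacement of a node in micrometres (+x = buccal)."""
    n = len(sol.node_displacements)
    if not 0 <= node < n:
        raise IndexError(f"node {node} out of range [0, {n})")
    return 1000.0 * sol.node_displacements[node]


# ---------------------------------------------------------------------------
# Verification meshes
# ---------------------------------------------------------------------------

def structured_rectangle(length: float, height: float, nx: int, ny: int,
                         region: str = "PATCH", crossed: bool = False) -> Mesh:
    """Rectangle [0, L] x [0, H] meshed with triangles; used by the analytic
    verification problems (patch test, cantilever).  ``crossed=True`` splits
    each quad into four triangles about its centre, which is markedly less
    stiff in bending than the two-triangle split."""
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    Xg, Yg = np.meshgrid(xs, ys)
    nodes = np.column_stack([Xg.ravel(), Yg.ravel()])

    def nid(i, j):
        return i * (nx + 1) + j

    tris = []
    if crossed:
        centres = []
        base = len(nodes)
        for i in range(ny):
            for j in range(nx):
                n00, n10 = nid(i, j), nid(i, j + 1)
                n01, n11 = nid(i + 1, j), nid(i + 1, j + 1)
                cidx = base + len(centres)
                centres.append(nodes[[n00, n10, n11, n01]].mean(axis=0))
                tris += [(n00, n10, cidx), (n10, n11, cidx),
                         (n11, n01, cidx), (n01, n00, cidx)]
        nodes = np.vstack([nodes, np.array(centres)])
    else:
        for i in range(ny):
            for j in range(nx):
                n00, n10 = nid(i, j), nid(i, j + 1)
                n01, n11 = nid(i + 1, j), nid(i + 1, j + 1)
                if (i + j) % 2 == 0:
                    tris += [(n00, n10, n11), (n00, n11, n01)]
                else:
                    tris += [(n00, n10, n01), (n10, n11, n01)]
    elements = np.array(tris, dtype=np.int64)
    region_arr = np.array([region] * len(elements), dtype=object)
    left = np.flatnonzero(nodes[:, 0] == 0.0)
    right = np.flatnonzero(nodes[:, 0] == length)
    boundary = np.flatnonzero(
        (nodes[:, 0] == 0.0) | (nodes[:, 0] == length)
        | (nodes[:, 1] == 0.0) | (nodes[:, 1] == height))
    node_sets = {"LEFT": left, "RIGHT": right, "BOUNDARY": boundary}
    return Mesh(nodes=nodes, elements=elements, element_region=region_arr,
                node_sets=node_sets, characteristic_length=length / nx)
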