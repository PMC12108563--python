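"""Linear-elastic finite-element solver for quadratic tetrahedral meshes.

Small-strain isotropic elasticity on C3D10 meshes with:

* exact 4-point Gauss integration (sufficient for quadratic displacement on
  straight-edged tets, so the patch test passes to round-off),
* Dirichlet fixation by elimination (prescribed values supported),
* bonded multi-point constraints (slave nodes interpolated on master facets
  with the quadratic facet shape functions; conforming interfaces need no
  equations at all),
* node-to-surface penalty contact with Coulomb friction resolved by an
  active-set / stick-slip fixed-point iteration.  The penalty normal law
  approximates a hard (non-penetration) contact; slip forces are applied as
  equal-and-opposite nodal pairs so global equilibrium is preserved exactly.

Units: mm / N / MPa.  Displacements in mm, stresses in MPa, Voigt order
(xx, yy, zz, xy, yz, zx) with engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import _closest_point_triangles
from .meshing import EDGES, TetMesh

__all__ = [
    "LoadCase",
    "ContactPair",
    "Solution",
    "element_stiffness",
    "assemble_stiffness",
    "distribute_load",
    "apply_bonded_mpc",
    "solve_linear",
    "solve_contact",
]

# 4-point Gauss rule of the reference tetrahedron (degree-2 exact)
_GA = 0.5854101966249685
_GB = 0.13819660112501052
GAUSS_BARY = np.full((4, 4), _GB)
np.fill_diagonal(GAUSS_BARY, _GA)
GAUSS_W = np.full(4, 1.0 / 24.0)  # includes the 1/6 reference volume

# natural-coordinate gradients of the barycentric coordinates
_DL = np.array([[-1.0, -1.0, -1.0],
                [1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0]])


def shape_gradients_natural(bary: np.ndarray) -> np.ndarray:
    """d N_i / d(xi, eta, zeta) of the 10 C3D10 shape functions, (10, 3)."""
    L = np.asarray(bary, dtype=float)
    dN = np.zeros((10, 3))
    for i in range(4):
        dN[i] = (4.0 * L[i] - 1.0) * _DL[i]
    for k, (a, b) in enumerate(EDGES):
        dN[4 + k] = 4.0 * (L[a] * _DL[b] + L[b] * _DL[a])
    return dN


def shape_functions(bary: np.ndarray) -> np.ndarray:
    """The 10 C3D10 shape functions at barycentric coordinates."""
    L = np.asarray(bary, dtype=float)
    N = np.zeros(10)
    for i in range(4):
        N[i] = L[i] * (2.0 * L[i] - 1.0)
    for k, (a, b) in enumerate(EDGES):
        N[4 + k] = 4.0 * L[a] * L[b]
    return N


_DN_NAT = np.stack([shape_gradients_natural(g) for g in GAUSS_BARY])  # (4,10,3)


def _elastic_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Batched isotropic elasticity matrices, (n, 6, 6)."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _element_B_detJ(coords: np.ndarray):
    """B matrices and Jacobian determinants at the 4 Gauss points.

    coords: (nel, 10, 3).  Returns B (nel, 4, 6, 30) and detJ (nel, 4).
    """
    nel = len(coords)
    B = np.zeros((nel, 4, 6, 30))
    detJ = np.empty((nel, 4))
    for g in range(4):
        dN = _DN_NAT[g]                       # (10, 3)
        J = np.einsum("ia,nib->nab", dN, coords)   # (nel, 3, 3)
        detJ[:, g] = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        dNx = np.einsum("ia,nba->nib", dN, invJ)   # dN/dx_b = invJ[b,a] dN/dxi_a
        B[:, g, 0, 0::3] = dNx[:, :, 0]
        B[:, g, 1, 1::3] = dNx[:, :, 1]
        B[:, g, 2, 2::3] = dNx[:, :, 2]
        B[:, g, 3, 0::3] = dNx[:, :, 1]
        B[:, g, 3, 1::3] = dNx[:, :, 0]
        B[:, g, 4, 1::3] = dNx[:, :, 2]
        B[:, g, 4, 2::3] = dNx[:, :, 1]
        B[:, g, 5, 0::3] = dNx[:, :, 2]
        B[:, g, 5, 2::3] = dNx[:, :, 0]
    return B, detJ


def element_stiffness(nodes10: np.ndarray, E: float, nu: float) -> np.ndarray:
    """30x30 stiffness of a single C3D10 element.

    Symmetric positive-semidefinite with exactly the 6 rigid-body
    zero-energy modes.  Raises for inverted (non-positive Jacobian)
    elements.
    """
    coords = np.asarray(nodes10, dtype=float).reshape(1, 10, 3)
    B, detJ = _element_B_detJ(coords)
    if np.any(detJ <= 0):
        raise ValueError("element has non-positive Jacobian (inverted)")
    D = _elastic_matrix([E], [nu])[0]
    K = np.zeros((30, 30))
    for g in range(4):
        Bg = B[0, g]
        K += GAUSS_W[g] * detJ[0, g] * Bg.T @ D @ Bg
    return 0.5 * (K + K.T)


def assemble_stiffness(mesh: TetMesh, materials, chunk: int = 20000):
    """Global sparse stiffness (CSR) assembled in element batches."""
    ndof = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []
    dof_map = (3 * mesh.elements[:, :, None]
               + np.arange(3)[None, None, :]).reshape(mesh.n_elements, 30)
    for s in range(0, mesh.n_elements, chunk):
        e = min(s + chunk, mesh.n_elements)
        coords = mesh.nodes[mesh.elements[s:e]]
        B, detJ = _element_B_detJ(coords)
        if np.any(detJ <= 0):
            bad = s + int(np.argwhere(detJ <= 0)[0, 0])
            raise ValueError(f"element {bad} has non-positive Jacobian")
        D = _elastic_matrix(materials.E[s:e], materials.nu[s:e])
        Ke = np.zeros((e - s, 30, 30))
        for g in range(4):
            Bg = B[:, g]
            DB = np.matmul(D, Bg)
            Ke += (GAUSS_W[g] * detJ[:, g])[:, None, None] * np.matmul(
                Bg.transpose(0, 2, 1), DB)
        dm = dof_map[s:e]
        rows.append(np.repeat(dm, 30, axis=1).ravel())
        cols.append(np.tile(dm, (1, 30)).ravel())
        vals.append(Ke.ravel())
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(ndof, ndof)).tocsr()
    return K


@dataclass
class ContactPair:
    """Node-to-surface contact definition between two separated bodies."""

    slave_nodes: np.ndarray       # node ids on the slave body surface
    master_facets: np.ndarray     # (k, 6) facet node ids on the master body
    mode: str = "frictional"      # "frictional" | "bonded" | "ignored"
    friction: float = 0.3
    penalty_scale: float = 50.0


@dataclass
class LoadCase:
    """Dirichlet sets, concentrated loads, ties and contact pairs.

    ``dirichlet``: list of {"set": name, "components": [0,1,2],
    "value": scalar or (n,3) array}.  ``loads``: list of {"set": name,
    "total": 3-vector in N} (node set -> equal split; surface set ->
    area-proportional facet lumping).  ``ties``: list of constraint dicts
    {"slave": node id, "masters": ids, "weights": w} (sum of weights 1).
    """

    dirichlet: list = field(default_factory=list)
    loads: list = field(default_factory=list)
    ties: list = field(default_factory=list)
    contact: list = field(default_factory=list)

    def validate(self, mesh: TetMesh) -> None:
        for d in self.dirichlet:
            ids = mesh.node_sets.get(d["set"])
            if ids is None or len(ids) == 0:
                raise ValueError(f"Dirichlet set {d['set']!r} missing or empty")
        for ld in self.loads:
            name = ld["set"]
            in_nodes = name in mesh.node_sets and len(mesh.node_sets[name]) > 0
            in_surf = name in mesh.surface_sets and len(mesh.surface_sets[name]) > 0
            if not (in_nodes or in_surf):
                raise ValueError(f"load set {name!r} missing or empty")
        for pair in self.contact:
            if pair.friction < 0:
                raise ValueError("friction coefficient must be >= 0")


@dataclass
class Solution:
    """Displacements, quadrature-point stresses and solver diagnostics."""

    displacements: np.ndarray        # (n_nodes, 3) mm
    stress: np.ndarray               # (n_el, 4, 6) MPa, Voigt
    reactions: np.ndarray            # (n_nodes, 3) N (nonzero at Dirichlet)
    applied: np.ndarray              # (n_nodes, 3) N external loads
    residual: float                  # relative equilibrium residual
    fixed_dofs: np.ndarray = None
    diagnostics: dict = field(default_factory=dict)

    def equilibrium_gap(self) -> np.ndarray:
        """Sum of reactions plus applied loads, per component (should be ~0)."""
        return self.reactions.sum(axis=0) + self.applied.sum(axis=0)


def distribute_load(mesh: TetMesh, set_name: str, total) -> np.ndarray:
    """Nodal load vector (n_nodes, 3) whose sum equals ``total`` exactly.

    Node sets split equally.  Surface sets weight facets by area and place
    each facet's share on its three midside nodes (the consistent load
    vector of a uniform traction on a straight-edged quadratic triangle).
    """
    total = np.asarray(total, dtype=float)
    f = np.zeros((mesh.n_nodes, 3))
    if set_name in mesh.node_sets and len(mesh.node_sets[set_name]):
        ids = mesh.node_sets[set_name]
        f[ids] = total / len(ids)
        return f
    if set_name in mesh.surface_sets and len(mesh.surface_sets[set_name]):
        facets = mesh.surface_sets[set_name]
        corners = mesh.nodes[facets[:, :3]]
        areas = 0.5 * np.linalg.norm(
            np.cross(corners[:, 1] - corners[:, 0],
                     corners[:, 2] - corners[:, 0]), axis=1)
        shares = areas / areas.sum()
        for k, facet in enumerate(facets):
            for mid in facet[3:]:
                f[mid] += total * shares[k] / 3.0
        return f
    raise ValueError(f"set {set_name!r} missing or empty")


def _facet_shape(bary3: np.ndarray) -> np.ndarray:
    """Quadratic triangle (T6) shape functions at barycentric (l1,l2,l3)."""
    l1, l2, l3 = bary3
    return np.array([l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
                     4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1])


def apply_bonded_mpc(mesh: TetMesh, slave_nodes: np.ndarray,
                     master_facets: np.ndarray,
                     capture_distance: float = None) -> list:
    """Tie slave nodes to master facets; returns LoadCase-style constraints.

    Conforming pairs (a slave node that is also a master-facet node) produce
    no equation.  Otherwise each slave is attached to its closest master
    facet through the quadratic facet interpolation, so a slave coincident
    with any master node is tied exactly and a tied pair moves as one body
    under rigid motion.  A slave farther than the capture distance is
    rejected with its location.
    """
    if capture_distance is None:
        edges = mesh.nodes[master_facets[:, 1]] - mesh.nodes[master_facets[:, 0]]
        capture_distance = 2.0 * np.linalg.norm(edges, axis=1).mean()
    master_node_set = set(np.unique(master_facets).tolist())
    tri = mesh.nodes[master_facets[:, :3]]
    constraints = []
    for s in np.asarray(slave_nodes):
        if int(s) in master_node_set:
            continue  # conforming: already merged
        p = mesh.nodes[s]
        P = np.repeat(p[None, :], len(tri), axis=0)
        cp = _closest_point_triangles(P, tri[:, 0], tri[:, 1], tri[:, 2])
        d2 = np.sum((cp - p) ** 2, axis=1)
        k = int(np.argmin(d2))
        dist = float(np.sqrt(d2[k]))
        if dist > capture_distance:
            raise ValueError(
                f"slave node {int(s)} at {p} is {dist:.3g} mm from the master "
                f"surface (capture distance {capture_distance:.3g} mm)")
        bary = _barycentric(cp[k], tri[k])
        w = _facet_shape(bary)
        keep = np.abs(w) > 1e-12
        constraints.append(dict(slave=int(s),
                                masters=master_facets[k][keep].copy(),
                                weights=w[keep].copy()))
    return constraints


def _barycentric(p, tri):
    a, b, c = tri
    v0, v1, v2 = b - a, c - a, p - a
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    den = d00 * d11 - d01 * d01
    l2 = (d11 * d20 - d01 * d21) / den
    l3 = (d00 * d21 - d01 * d20) / den
    return np.array([1.0 - l2 - l3, l2, l3])


def _tie_transform(ndof: int, ties: list) -> sp.csr_matrix:
    """Sparse T with u_full = T u_reduced eliminating slave dofs."""
    slave_dofs = set()
    for t in ties:
        for c in range(3):
            slave_dofs.add(3 * t["slave"] + c)
    keep = np.array([d for d in range(ndof) if d not in slave_dofs],
                    dtype=np.int64)
    col_of = -np.ones(ndof, dtype=np.int64)
    col_of[keep] = np.arange(len(keep))
    rows, cols, vals = list(keep), list(range(len(keep))), [1.0] * len(keep)
    for t in ties:
        for c in range(3):
            sd = 3 * t["slave"] + c
            for m, w in zip(t["masters"], t["weights"]):
                md = 3 * int(m) + c
                if col_of[md] < 0:
                    raise ValueError("chained ties are not supported "
                                     "(a master node is itself a slave)")
                rows.append(sd)
                cols.append(col_of[md])
                vals.append(float(w))
    T = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, len(keep))).tocsr()
    return T


def _collect_bc(mesh: TetMesh, loadcase: LoadCase):
    ndof = 3 * mesh.n_nodes
    fixed = {}
    for d in loadcase.dirichlet:
        ids = mesh.node_sets[d["set"]]
        comps = d.get("components", (0, 1, 2))
        value = d.get("value", 0.0)
        value = np.asarray(value, dtype=float)
        for j, nid in enumerate(ids):
            for c in comps:
                if value.ndim == 0:
                    fixed[3 * nid + c] = float(value)
                else:
                    fixed[3 * nid + c] = float(value[j, c])
    f = np.zeros((mesh.n_nodes, 3))
    for ld in loadcase.loads:
        f += distribute_load(mesh, ld["set"], ld["total"])
    return fixed, f


class _ReducedSolver:
    """Tie + Dirichlet reduction with a reusable factorization.

    Factors once; :meth:`solve` then handles any number of right-hand sides
    (used by the contact iteration, whose slip forces change while the
    stiffness does not).
    """

    def __init__(self, K: sp.csr_matrix, fixed: dict, ties: list, ndof: int,
                 method: str = "auto", cg_threshold: int = 400_000):
        self.K = K
        self.T = (_tie_transform(ndof, ties) if ties
                  else sp.identity(ndof, format="csr"))
        self.Kr = (self.T.T @ K @ self.T).tocsr()
        self.fixed_dofs = np.array(sorted(fixed), dtype=np.int64)
        self.fixed_vals = np.array([fixed[d] for d in self.fixed_dofs])
        if len(self.fixed_dofs) < 6:
            raise ValueError("fewer than 6 constrained dofs; "
                             "rigid-body motion makes the system singular")
        # map full fixed dofs to reduced indices (Dirichlet nodes not slaves)
        col_of = (np.asarray(self.T.argmax(axis=1)).ravel() if ties
                  else np.arange(ndof))
        self.red_fixed = col_of[self.fixed_dofs]
        nred = self.Kr.shape[0]
        mask = np.ones(nred, dtype=bool)
        mask[self.red_fixed] = False
        self.free = np.nonzero(mask)[0]
        self.Kff = self.Kr[self.free][:, self.free]
        self.Kfc = self.Kr[self.free][:, self.red_fixed]
        self.use_cg = method == "cg" or (method == "auto"
                                         and len(self.free) > cg_threshold)
        if self.use_cg:
            self.M = sp.diags(1.0 / self.Kff.diagonal())
            self.lu = None
        else:
            try:
                self.lu = spla.splu(self.Kff.tocsc())
            except RuntimeError as exc:
                raise ValueError(
                    f"singular system (insufficient constraints?): {exc}")

    def solve(self, f_total: np.ndarray):
        """Returns (u (n,3), reactions (n,3), relative residual)."""
        fr = self.T.T @ f_total.ravel()
        rhs = fr[self.free] - self.Kfc @ self.fixed_vals
        if self.use_cg:
            x, info = spla.cg(self.Kff.tocsr(), rhs, M=self.M, rtol=1e-10,
                              maxiter=20000)
            if info != 0:
                raise RuntimeError(f"CG failed to converge (info={info})")
        else:
            x = self.lu.solve(rhs)
        nred = self.Kr.shape[0]
        u_red = np.zeros(nred)
        u_red[self.red_fixed] = self.fixed_vals
        u_red[self.free] = x
        u = self.T @ u_red
        resid_full = self.K @ u - f_total.ravel()
        reactions = np.zeros_like(u)
        reactions[self.fixed_dofs] = resid_full[self.fixed_dofs]
        r_red = self.Kr @ u_red - fr
        r_red[self.red_fixed] = 0.0
        fnorm = np.linalg.norm(fr) + np.linalg.norm(reactions)
        residual = (np.linalg.norm(r_red) / fnorm if fnorm > 0
                    else np.linalg.norm(r_red))
        return u.reshape(-1, 3), reactions.reshape(-1, 3), residual


def _solve_system(K: sp.csr_matrix, f: np.ndarray, fixed: dict,
                  ties: list, ndof: int, method: str = "auto",
                  cg_threshold: int = 400_000, extra_forces=None):
    """Reduce by ties + Dirichlet, solve, expand; returns (u, reactions)."""
    f_total = f.copy().ravel()
    if extra_forces is not None:
        f_total = f_total + extra_forces
    solver = _ReducedSolver(K, fixed, ties, ndof, method, cg_threshold)
    u, reactions, residual = solver.solve(f_total)
    return u, reactions, residual, solver.fixed_dofs


def recover_stresses(mesh: TetMesh, materials, u: np.ndarray,
                     chunk: int = 20000) -> np.ndarray:
    """Quadrature-point stresses (n_el, 4, 6) from the displacement field."""
    stress = np.empty((mesh.n_elements, 4, 6))
    dof = u.reshape(-1, 3)
    for s in range(0, mesh.n_elements, chunk):
        e = min(s + chunk, mesh.n_elements)
        coords = mesh.nodes[mesh.elements[s:e]]
        B, _ = _element_B_detJ(coords)
        ue = dof[mesh.elements[s:e]].reshape(e - s, 30)
        D = _elastic_matrix(materials.E[s:e], materials.nu[s:e])
        for g in range(4):
            eps = np.einsum("nij,nj->ni", B[:, g], ue)
            stress[s:e, g] = np.einsum("nij,nj->ni", D, eps)
    return stress


def solve_linear(mesh: TetMesh, materials, loadcase: LoadCase,
                 method: str = "auto", residual_tol: float = 1e-8) -> Solution:
    """Solve K u = f with Dirichlet fixation and bonded ties (no contact)."""
    loadcase.validate(mesh)
    K = assemble_stiffness(mesh, materials)
    fixed, f = _collect_bc(mesh, loadcase)
    u, reactions, residual, fixed_dofs = _solve_system(
        K, f, fixed, loadcase.ties, 3 * mesh.n_nodes, method)
    if residual > residual_tol:
        raise RuntimeError(f"equilibrium residual {residual:.2e} exceeds "
                           f"{residual_tol:.0e}")
    stress = recover_stresses(mesh, materials, u)
    return Solution(displacements=u, stress=stress, reactions=reactions,
                    applied=f, residual=residual, fixed_dofs=fixed_dofs,
                    diagnostics={"method": method})


def _contact_geometry(mesh: TetMesh, pair: ContactPair):
    """Reference-configuration projection of each slave node on the master.

    Returns per-slave-node: master facet index, interpolation weights over
    the facet's 6 nodes, unit outward normal of the master facet, initial
    gap and tributary penalty area.
    """
    tri = mesh.nodes[pair.master_facets[:, :3]]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(normals, axis=1)
    normals = normals / (2 * areas)[:, None]

    slaves = np.asarray(pair.slave_nodes)
    info = []
    for s in slaves:
        p = mesh.nodes[s]
        P = np.repeat(p[None, :], len(tri), axis=0)
        cp = _closest_point_triangles(P, tri[:, 0], tri[:, 1], tri[:, 2])
        d2 = np.sum((cp - p) ** 2, axis=1)
        k = int(np.argmin(d2))
        n = normals[k]
        g0 = float((p - cp[k]) @ n)
        bary = _barycentric(cp[k], tri[k])
        w = _facet_shape(bary)
        info.append(dict(slave=int(s), facet=k, weights=w,
                         nodes=pair.master_facets[k], normal=n, gap0=g0,
                         area=areas[k] / 3.0))
    return info


def solve_contact(mesh: TetMesh, materials, loadcase: LoadCase,
                  method: str = "auto", max_outer: int = 40,
                  residual_tol: float = 1e-6, verbose: bool = False) -> Solution:
    """Solve with penalty normal contact and Coulomb stick/slip friction.

    Outer fixed-point iteration: project slave nodes (reference
    configuration), activate penetrating nodes with a normal penalty spring,
    keep stuck nodes under a tangential penalty and release sliding nodes to
    the Coulomb force mu*|N| applied as an equal-opposite nodal pair.
    Converged when the active and slip sets are stable and the displacement
    update is below tolerance; non-convergence raises with the last state.
    """
    pairs = [p for p in loadcase.contact if p.mode == "frictional"]
    bonded = [p for p in loadcase.contact if p.mode == "bonded"]
    ties = list(loadcase.ties)
    for p in bonded:
        ties.extend(apply_bonded_mpc(mesh, p.slave_nodes, p.master_facets))
    if not pairs:
        lc = LoadCase(dirichlet=loadcase.dirichlet, loads=loadcase.loads,
                      ties=ties)
        return solve_linear(mesh, materials, lc, method=method)

    loadcase.validate(mesh)
    K0 = assemble_stiffness(mesh, materials)
    fixed, f = _collect_bc(mesh, loadcase)
    ndof = 3 * mesh.n_nodes

    edge = mesh.nodes[mesh.elements[:, 1]] - mesh.nodes[mesh.elements[:, 0]]
    h_edge = float(np.linalg.norm(edge, axis=1).mean())
    E_max = float(np.max(materials.E))
    gap_tol = 1e-3 * h_edge

    geom = []
    for pair in pairs:
        info = _contact_geometry(mesh, pair)
        kn = pair.penalty_scale * E_max * np.array([c["area"] for c in info]) / h_edge
        geom.append((pair, info, kn))

    def constraint_vectors(info):
        """Sparse rows c with c.u = relative displacement component."""
        rows = []
        for c in info:
            idx = [3 * c["slave"] + d for d in range(3)]
            coef_s = np.eye(3)
            idx_m, coef_m = [], []
            for m, w in zip(c["nodes"], c["weights"]):
                for d in range(3):
                    idx_m.append(3 * int(m) + d)
                coef_m.append(-w * np.eye(3))
            rows.append((np.array(idx + idx_m),
                         np.vstack([coef_s] + coef_m)))  # (3+6*3, 3)
        return rows

    crows_all = [constraint_vectors(info) for (_, info, _) in geom]

    def evaluate_sets(u, first):
        """Active (penetrating/touching) nodes and their stick/slip state."""
        touch_tol = 1e-9 * h_edge if first else 0.0
        active = []
        for gi, (pair, info, kn) in enumerate(geom):
            kt = 0.1 * kn
            for ci, (c, (idx, coef)) in enumerate(zip(info, crows_all[gi])):
                rel = coef.T @ u[idx]
                gap = c["gap0"] + rel @ c["normal"]
                if gap >= touch_tol:
                    continue
                active.append((gi, ci))
        return active

    def classify_slip(u, active, slip_state):
        """Hysteresis stick/slip update at the displacement state u."""
        slip = []
        for (gi, ci) in active:
            pair, info, kn = geom[gi]
            if pair.friction == 0.0:
                continue
            c = info[ci]
            idx, coef = crows_all[gi][ci]
            n = c["normal"]
            rel = coef.T @ u[idx]
            gap = c["gap0"] + rel @ n
            fn = max(kn[ci] * escalation * (-gap), 0.0)
            t_rel = rel - (rel @ n) * n
            t_norm = np.linalg.norm(t_rel)
            ft_trial = 0.1 * kn[ci] * escalation * t_norm
            limit = pair.friction * fn
            if slip_state.get((gi, ci), False):
                now_slip = ft_trial >= 0.95 * limit
            else:
                now_slip = ft_trial > 1.05 * limit
            slip_state[(gi, ci)] = now_slip and t_norm > 1e-14
            if slip_state[(gi, ci)]:
                slip.append((gi, ci))
        return slip

    def assemble_contact(active):
        """Penalty stiffness (normal + tangential) and constant forces."""
        rows, cols, vals = [], [], []
        f_const = np.zeros(ndof)
        for (gi, ci) in active:
            pair, info, kn = geom[gi]
            c = info[ci]
            idx, coef = crows_all[gi][ci]
            n = c["normal"]
            kni = kn[ci] * escalation
            cn = coef @ n
            rows.append(np.repeat(idx, len(idx)))
            cols.append(np.tile(idx, len(idx)))
            vals.append((kni * np.outer(cn, cn)).ravel())
            f_const[idx] += -kni * c["gap0"] * cn
            if pair.friction > 0.0:
                t1 = _any_perp(n)
                t2 = np.cross(n, t1)
                kti = 0.1 * kni
                for t in (t1, t2):
                    ct = coef @ t
                    rows.append(np.repeat(idx, len(idx)))
                    cols.append(np.tile(idx, len(idx)))
                    vals.append((kti * np.outer(ct, ct)).ravel())
        Kc = (sp.coo_matrix((np.concatenate(vals),
                             (np.concatenate(rows), np.concatenate(cols))),
                            shape=(ndof, ndof)).tocsr() if vals else None)
        return Kc, f_const

    def slip_forces(u, slip):
        """Radial-return corrections: cap |f_t| at mu*|N| for sliding nodes."""
        f_slip = np.zeros(ndof)
        for (gi, ci) in slip:
            pair, info, kn = geom[gi]
            c = info[ci]
            idx, coef = crows_all[gi][ci]
            n = c["normal"]
            rel = coef.T @ u[idx]
            gap = c["gap0"] + rel @ n
            fn = max(kn[ci] * escalation * (-gap), 0.0)
            t_rel = rel - (rel @ n) * n
            t_norm = np.linalg.norm(t_rel)
            if t_norm < 1e-14:
                continue
            ft_trial = 0.1 * kn[ci] * escalation * t_norm
            excess = ft_trial - pair.friction * fn
            if excess > 0:
                f_slip[idx] += coef @ (excess * t_rel / t_norm)
        return f_slip

    u = np.zeros(ndof)
    slip_state = {}
    active_prev, slip_prev = None, None
    escalation = 1.0
    iters = 0
    inner_total = 0
    for outer in range(1, max_outer + 1):
        iters = outer
        active = evaluate_sets(u, first=(outer == 1))
        slip = classify_slip(u, active, slip_state)
        Kc, f_const = assemble_contact(active)
        K = K0 + Kc if Kc is not None else K0
        solver = _ReducedSolver(K, fixed, ties, ndof, method)
        # inner fixed point on the slip forces, reusing the factorization;
        # Aitken under-relaxation accelerates the slowly contracting map
        du = np.inf
        lam = 0.5
        r_prev = None
        for inner in range(200):
            inner_total += 1
            f_slip = slip_forces(u, slip)
            u_new, reactions, residual = solver.solve(f.ravel() + f_const + f_slip)
            un = u_new.ravel()
            r = un - u
            du = np.linalg.norm(r) / (np.linalg.norm(un) + 1e-30)
            if du < 0.1 * residual_tol or not slip:
                u = un
                break
            if inner == 0:
                u = un
            else:
                dr = r - r_prev
                denom = float(dr @ dr)
                if denom > 0:
                    lam = -lam * float(r_prev @ dr) / denom
                    lam = min(max(lam, 0.1), 2.0)
                u = u + lam * r
            r_prev = r
        else:
            u = un
        if verbose:
            print(f"contact outer {outer}: du={du:.3e} active={len(active)} "
                  f"slip={len(slip)} inner={inner + 1} residual={residual:.2e}")
        sets_stable = (active == active_prev) and (slip == slip_prev)
        active_prev, slip_prev = active, slip
        # re-evaluate sets at the converged state
        new_active = evaluate_sets(u, first=False)
        new_slip = classify_slip(u, new_active, dict(slip_state))
        if sets_stable and new_active == active and new_slip == slip:
            max_pen = 0.0
            for gi, (pair, info, kn) in enumerate(geom):
                for c, (idx, coef) in zip(info, crows_all[gi]):
                    gap = c["gap0"] + (coef.T @ u[idx]) @ c["normal"]
                    max_pen = max(max_pen, -gap)
            if max_pen > gap_tol and escalation < 1000.0:
                escalation *= 10.0
                active_prev = None
                continue
            f_extra = f_const + slip_forces(u, slip)
            stress = recover_stresses(mesh, materials, u.reshape(-1, 3))
            return Solution(
                displacements=u.reshape(-1, 3), stress=stress,
                reactions=reactions, applied=f + f_extra.reshape(-1, 3),
                residual=residual, fixed_dofs=solver.fixed_dofs,
                diagnostics={"contact_iterations": iters,
                             "inner_iterations": inner_total,
                             "active_nodes": len(active),
                             "slipping_nodes": len(slip),
                             "max_penetration": max_pen,
                             "penalty_escalation": escalation})
    raise RuntimeError(
        f"contact iteration did not converge in {max_outer} outer steps "
        f"(last displacement update {du:.2e}, active {len(active)})")


def _any_perp(n: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t = np.cross(n, a)
    return t / np.linalg.norm(t)
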