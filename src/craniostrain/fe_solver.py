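"""Multi-material linear-elastic statics on labelled tetrahedral meshes.

Small-strain, isotropic, homogeneous-per-material elasticity with 4-node
(constant-strain) and 10-node (quadratic) tetrahedra, assembled into a
scipy CSR stiffness matrix.  Muscle wrapping paths become chains of axial
truss ("link") elements tied to the mesh surface.  Constraint schemes pin
six scalar degrees of freedom per bite (bite-point plus the two jaw-joint
contact nodes), the minimum that suppresses rigid-body motion without
over-constraining lateral deformation.

Anatomical axes: x mediolateral, y anteroposterior, z dorsoventral.
Units: mm, N, MPa; strains are returned in microstrain (µε).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from craniostrain.mesh import LabeledTetMesh, MeshError, surface_node_ids

__all__ = [
    "MaterialTable",
    "ConstraintScheme",
    "StrainField",
    "FESystem",
    "SingularSystemError",
    "assemble_system",
    "add_link_elements",
    "solve_static",
    "element_strains",
    "von_mises_strain",
    "run_load_case",
    "AXIS",
]

#: anatomical axis names -> coordinate index
AXIS = {"ml": 0, "ap": 1, "dv": 2, "x": 0, "y": 1, "z": 2}

#: default per-material elastic constants (E in MPa, Poisson's ratio)
DEFAULT_MATERIALS: dict[str, tuple[float, float]] = {
    "bone": (13_700.0, 0.3),
    "tooth": (19_890.0, 0.31),
    "pdl": (50.0, 0.49),
    "suture": (20.0, 0.49),
    "pulp": (2.0, 0.49),
    "link": (13_700.0, 0.3),  # links transfer force with minimal deformation
}


class SingularSystemError(RuntimeError):
    """The constrained stiffness matrix is singular (under-constrained)."""


@dataclass
class MaterialTable:
    """Young's modulus (MPa) and Poisson's ratio per material label.

    Invalid constants (E <= 0 or ν outside [0, 0.5)) are reported by
    :meth:`findings` and rejected when an elastic matrix is requested, so a
    config can be inspected without raising.
    """

    materials: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MATERIALS))

    def findings(self) -> list[str]:
        out = []
        for lab, (E, nu) in self.materials.items():
            if E <= 0:
                out.append(f"material {lab!r}: non-positive Young's modulus {E}")
            if not 0.0 <= nu < 0.5:
                out.append(f"material {lab!r}: Poisson's ratio {nu} outside [0, 0.5)")
        return out

    def __getitem__(self, label: str) -> tuple[float, float]:
        try:
            return self.materials[label]
        except KeyError:
            raise KeyError(f"material {label!r} missing from the material table") from None

    def elastic_matrix(self, label: str) -> np.ndarray:
        """6x6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
        E, nu = self[label]
        if E <= 0 or not 0.0 <= nu < 0.5:
            raise ValueError(f"material {label!r}: invalid constants E={E}, nu={nu}")
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu  # engineering shear
        return D

    def scaled(self, multipliers: dict[str, float]) -> "MaterialTable":
        """Copy with Young's moduli multiplied per label (sensitivity runs)."""
        mats = dict(self.materials)
        for lab, m in multipliers.items():
            if m <= 0:
                raise ValueError(f"stiffness multiplier for {lab!r} must be > 0")
            E, nu = self[lab]
            mats[lab] = (E * m, nu)
        return MaterialTable(mats)


# ---------------------------------------------------------------------------
# element matrices

# dN/dxi of the 4 barycentric coordinates
_DLAM = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])

# 4-point Gauss rule on the reference tet (degree 2), barycentric coords
_GA, _GB = 0.5854101966249685, 0.13819660112501052
_GAUSS4 = np.array([
    [_GA, _GB, _GB, _GB],
    [_GB, _GA, _GB, _GB],
    [_GB, _GB, _GA, _GB],
    [_GB, _GB, _GB, _GA],
])

from craniostrain.mesh import QUADRATIC_EDGES


def _tet10_dshape(lam: np.ndarray) -> np.ndarray:
    """(10, 3) shape-function xi-gradients at barycentric point ``lam``."""
    d = np.zeros((10, 3))
    for i in range(4):
        d[i] = (4 * lam[i] - 1) * _DLAM[i]
    for k, (a, b) in enumerate(QUADRATIC_EDGES):
        d[4 + k] = 4 * (lam[a] * _DLAM[b] + lam[b] * _DLAM[a])
    return d


def _grads_to_B(G: np.ndarray) -> np.ndarray:
    """Map (n, nn, 3) shape gradients to (n, 6, 3*nn) strain-displacement B."""
    n, nn, _ = G.shape
    B = np.zeros((n, 6, 3 * nn))
    gx, gy, gz = G[:, :, 0], G[:, :, 1], G[:, :, 2]
    cols = np.arange(nn)
    B[:, 0, 3 * cols + 0] = gx
    B[:, 1, 3 * cols + 1] = gy
    B[:, 2, 3 * cols + 2] = gz
    B[:, 3, 3 * cols + 0] = gy
    B[:, 3, 3 * cols + 1] = gx
    B[:, 4, 3 * cols + 1] = gz
    B[:, 4, 3 * cols + 2] = gy
    B[:, 5, 3 * cols + 0] = gz
    B[:, 5, 3 * cols + 2] = gx
    return B


def _element_geometry(mesh: LabeledTetMesh):
    """Per-element corner Jacobians: inv(A) (n,3,3) and volumes (n,)."""
    p = mesh.nodes[mesh.elements[:, :4]]
    A = (p[:, 1:] - p[:, :1]).transpose(0, 2, 1)  # columns p_i - p_0
    det = np.linalg.det(A)
    if np.any(det <= 0):
        bad = int(np.argmax(det <= 0))
        raise MeshError(f"element {bad}: non-positive Jacobian")
    return np.linalg.inv(A), det / 6.0


def _element_B_gauss(mesh: LabeledTetMesh):
    """B operators per Gauss point: list of (n, 6, 3*nn), plus volumes."""
    invA, vol = _element_geometry(mesh)
    if mesh.order == 1:
        G = np.einsum("aj,njk->nak", _DLAM[:, :], invA)  # constant gradients
        return [_grads_to_B(G)], vol
    Bs = []
    for lam in _GAUSS4:
        dN = _tet10_dshape(lam)
        G = np.einsum("aj,njk->nak", dN, invA)
        Bs.append(_grads_to_B(G))
    return Bs, vol


def _material_D_stack(mesh: LabeledTetMesh, materials: MaterialTable) -> np.ndarray:
    labels = np.unique(mesh.material)
    D = np.zeros((mesh.n_elements, 6, 6))
    for lab in labels:
        D[mesh.material == lab] = materials.elastic_matrix(str(lab))
    return D


@dataclass
class FESystem:
    """Assembled stiffness operator plus bookkeeping.

    ``coords`` covers mesh nodes plus any extra link-joint nodes appended by
    :func:`add_link_elements`; ``n_mesh_nodes`` marks the boundary.
    """

    K: sp.csr_matrix
    coords: np.ndarray
    n_mesh_nodes: int

    @property
    def ndof(self) -> int:
        return 3 * self.coords.shape[0]


def assemble_system(mesh: LabeledTetMesh, materials: MaterialTable) -> FESystem:
    """Assemble the global stiffness matrix (symmetric positive semi-definite
    with exactly six rigid-body zero-energy modes before constraints)."""
    Bs, vol = _element_B_gauss(mesh)
    D = _material_D_stack(mesh, materials)
    w = 1.0 / len(Bs)
    nn = mesh.elements.shape[1]
    Ke = np.zeros((mesh.n_elements, 3 * nn, 3 * nn))
    for B in Bs:
        Ke += w * np.einsum("nia,nij,njb->nab", B, D, B, optimize=True)
    Ke *= vol[:, None, None]

    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(mesh.n_elements, 3 * nn)
    rows = np.repeat(edof, 3 * nn, axis=1).ravel()
    cols = np.tile(edof, (1, 3 * nn)).ravel()
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return FESystem(K=K, coords=mesh.nodes.copy(), n_mesh_nodes=mesh.n_nodes)


# ---------------------------------------------------------------------------
# link (truss) elements for muscle wrapping


def _truss_triplets(i: int, j: int, coords_i, coords_j, k_axial: float):
    d = np.asarray(coords_j, float) - np.asarray(coords_i, float)
    L = np.linalg.norm(d)
    u = d / L
    kblock = k_axial * np.outer(u, u)
    dofs_i = [3 * i, 3 * i + 1, 3 * i + 2]
    dofs_j = [3 * j, 3 * j + 1, 3 * j + 2]
    rows, cols, vals = [], [], []
    for a in range(3):
        for b in range(3):
            for (ra, ca, s) in ((dofs_i[a], dofs_i[b], 1), (dofs_j[a], dofs_j[b], 1),
                                (dofs_i[a], dofs_j[b], -1), (dofs_j[a], dofs_i[b], -1)):
                rows.append(ra)
                cols.append(ca)
                vals.append(s * kblock[a, b])
    return rows, cols, vals


def add_link_elements(system: FESystem, paths: list[np.ndarray],
                      E_link: float = DEFAULT_MATERIALS["link"][0],
                      area: float = 1.0, snap_tol: float = 1e-6,
                      anchor_max: float = 3.0,
                      regularization: float = 1e-6) -> FESystem:
    """Augment the system with truss chains along muscle wrapping paths.

    Each path is a polyline of points on (or very near) the mesh surface.
    Points coinciding with a surface node reuse it; other points become new
    joint nodes tied to the nearest surface node by a short anchor truss
    oriented along the joint-to-surface direction.  Trusses carry axial
    force only; a weak isotropic spring (``regularization`` times the
    anchor's axial stiffness) suppresses the lateral zero-energy mode of
    floating joints, with negligible effect on force transfer.

    Raises
    ------
    MeshError
        If a path point lies farther than ``anchor_max`` from the surface,
        or a segment has (near-)zero length.
    """
    surf = surface_node_ids_from_system(system)
    tree = cKDTree(system.coords[surf])
    rows: list = []
    cols: list = []
    vals: list = []
    n0 = system.coords.shape[0]
    all_xyz = list(system.coords)

    def point_id(p: np.ndarray) -> int:
        p = np.asarray(p, float)
        dist, k = tree.query(p)
        if dist <= snap_tol:
            return int(surf[k])
        if dist > anchor_max:
            raise MeshError(f"wrapping path point {tuple(p)} is not on the surface "
                            f"(distance {dist:.3g} mm)")
        j = len(all_xyz)
        all_xyz.append(p)
        anchor = int(surf[k])
        ka = E_link * area / max(dist, 1e-9)
        r, c, v = _truss_triplets(j, anchor, p, system.coords[anchor], ka)
        rows.extend(r), cols.extend(c), vals.extend(v)
        # weak spring: ties all three joint DOFs, kills the transverse mode
        kw = regularization * ka
        for a in range(3):
            for (ra, ca, s) in ((3 * j + a, 3 * j + a, 1), (3 * anchor + a, 3 * anchor + a, 1),
                                (3 * j + a, 3 * anchor + a, -1), (3 * anchor + a, 3 * j + a, -1)):
                rows.append(ra)
                cols.append(ca)
                vals.append(s * kw)
        return j

    for path in paths:
        pts = np.asarray(path, float)
        if pts.ndim != 2 or len(pts) < 2:
            raise MeshError("each wrapping path needs at least two points")
        ids = [point_id(p) for p in pts]
        for (i, j), (pi, pj) in zip(zip(ids[:-1], ids[1:]), zip(pts[:-1], pts[1:])):
            L = np.linalg.norm(pj - pi)
            if L < 1e-9:
                raise MeshError("zero-length wrapping-path segment")
            r, c, v = _truss_triplets(i, j, pi, pj, E_link * area / L)
            rows.extend(r), cols.extend(c), vals.extend(v)

    coords_all = np.asarray(all_xyz)
    ndof = 3 * coords_all.shape[0]
    K0 = system.K.tocoo()
    K = sp.coo_matrix((K0.data, (K0.row, K0.col)), shape=(ndof, ndof)).tocsr()
    if rows:
        K = K + sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return FESystem(K=K, coords=coords_all, n_mesh_nodes=system.n_mesh_nodes)


def surface_node_ids_from_system(system: FESystem) -> np.ndarray:
    """Surface nodes recorded on the system (set at assembly time)."""
    if not hasattr(system, "_surface_ids"):
        raise MeshError("system has no surface information; assemble via run_load_case "
                        "or attach mesh surface ids first")
    return system._surface_ids


def attach_surface(system: FESystem, mesh: LabeledTetMesh) -> FESystem:
    """Record the mesh's surface corner nodes on the system (for links)."""
    system._surface_ids = surface_node_ids(mesh)
    return system


# ---------------------------------------------------------------------------
# constraints and solve


@dataclass
class ConstraintScheme:
    """Homogeneous (or prescribed) single-DOF constraints.

    ``entries`` is a list of ``(node_id, axis, value)`` with axis in 0..2.
    The bite schemes always carry exactly six scalar constraints.
    """

    entries: list[tuple[int, int, float]]
    tag: str = ""

    @classmethod
    def for_bite(cls, mode: str, bite_node: int, working_tmj: int,
                 balancing_tmj: int) -> "ConstraintScheme":
        """Six-DOF bite constraint set.

        molar: bite {dv}, working TMJ {dv, ap}, balancing TMJ {ml, ap, dv};
        incisor: bite {dv}, working TMJ {ml, ap, dv}, balancing TMJ {dv, ap}.
        """
        dv, ap, ml = AXIS["dv"], AXIS["ap"], AXIS["ml"]
        if mode == "molar":
            ax = [(bite_node, dv), (working_tmj, dv), (working_tmj, ap),
                  (balancing_tmj, ml), (balancing_tmj, ap), (balancing_tmj, dv)]
        elif mode == "incisor":
            ax = [(bite_node, dv), (working_tmj, ml), (working_tmj, ap),
                  (working_tmj, dv), (balancing_tmj, dv), (balancing_tmj, ap)]
        else:
            raise ValueError(f"unknown bite mode {mode!r}")
        return cls(entries=[(n, a, 0.0) for n, a in ax], tag=mode)

    def dofs(self) -> np.ndarray:
        return np.array([3 * n + a for n, a, _ in self.entries], dtype=np.int64)

    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.entries], dtype=float)


def solve_static(system: FESystem, constraints: ConstraintScheme,
                 loads: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve K u = f with single-DOF Dirichlet constraints.

    Returns ``(u, reactions)`` where reactions = K u − f is nonzero only at
    constrained DOFs (global equilibrium: Σ reactions = −Σ applied loads).
    """
    f = np.zeros(system.ndof)
    f[: len(loads)] = loads
    fixed = constraints.dofs()
    if len(np.unique(fixed)) != len(fixed):
        raise ValueError("duplicate constraint DOFs")
    uc = constraints.values()
    free = np.setdiff1d(np.arange(system.ndof), fixed)
    K = system.K
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed] @ uc
    try:
        lu = spla.splu(Kff)
        piv = np.abs(lu.U.diagonal())
        if piv.size and piv.min() < 1e-10 * piv.max():
            raise SingularSystemError(
                "stiffness matrix is singular (near-zero pivot): the constraint "
                "set does not remove all rigid-body modes")
        uf = lu.solve(rhs)
    except RuntimeError as err:
        raise SingularSystemError(f"stiffness matrix is singular: {err}") from err
    if not np.all(np.isfinite(uf)):
        raise SingularSystemError("singular or ill-posed system (non-finite solution); "
                                  "check that constraints remove all rigid-body modes")
    u = np.zeros(system.ndof)
    u[free] = uf
    u[fixed] = uc
    reactions = K @ u - f
    reactions[free] = 0.0
    return u, reactions


# ---------------------------------------------------------------------------
# strain recovery


def von_mises_strain(e1, e2, e3, nu_eff):
    """Equivalent (von Mises) strain from principal strains.

    ε_vM = sqrt(((ε1−ε2)² + (ε2−ε3)² + (ε3−ε1)²) / 2) / (1 + ν_eff),
    the effective-Poisson's-ratio convention of commercial FE solvers; it
    recovers the axial strain for a uniaxial state and vanishes for
    hydrostatic states.
    """
    e1, e2, e3 = np.broadcast_arrays(e1, e2, e3)
    return np.sqrt(((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2) / 2.0) / (
        1.0 + np.asarray(nu_eff))


@dataclass
class StrainField:
    """Per-element strain state for one load case (all in µε)."""

    regime_id: str
    voigt: np.ndarray       #: (n, 6) engineering strains (xx, yy, zz, xy, yz, zx)
    principal: np.ndarray   #: (n, 3) principal strains, descending
    von_mises: np.ndarray   #: (n,) equivalent strain
    mode: str = ""          #: bite mode of the generating regime

    def tensors(self) -> np.ndarray:
        """(n, 3, 3) symmetric strain tensors (tensor shear = γ/2)."""
        v = self.voigt
        t = np.zeros((len(v), 3, 3))
        t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = v[:, 0], v[:, 1], v[:, 2]
        t[:, 0, 1] = t[:, 1, 0] = v[:, 3] / 2
        t[:, 1, 2] = t[:, 2, 1] = v[:, 4] / 2
        t[:, 0, 2] = t[:, 2, 0] = v[:, 5] / 2
        return t


def element_strains(u: np.ndarray, mesh: LabeledTetMesh,
                    materials: MaterialTable | None = None,
                    nu_eff: float | None = None,
                    regime_id: str = "", mode: str = "") -> StrainField:
    """Per-element strains from a displacement field.

    Linear tets give the (constant) centroid strain; quadratic tets the
    average over the four interior quadrature points.  ``nu_eff`` overrides
    the per-element material Poisson's ratio in the von Mises combination.
    """
    Bs, _vol = _element_B_gauss(mesh)
    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(mesh.n_elements, -1)
    ue = u[edof]
    voigt = np.zeros((mesh.n_elements, 6))
    for B in Bs:
        voigt += np.einsum("nij,nj->ni", B, ue) / len(Bs)
    voigt_ue = voigt * 1e6  # -> µε

    t = np.zeros((mesh.n_elements, 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = voigt_ue[:, 0], voigt_ue[:, 1], voigt_ue[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = voigt_ue[:, 3] / 2
    t[:, 1, 2] = t[:, 2, 1] = voigt_ue[:, 4] / 2
    t[:, 0, 2] = t[:, 2, 0] = voigt_ue[:, 5] / 2
    principal = np.linalg.eigvalsh(t)[:, ::-1]  # descending

    if nu_eff is not None:
        nu = np.full(mesh.n_elements, float(nu_eff))
    else:
        materials = materials or MaterialTable()
        nu = np.empty(mesh.n_elements)
        for lab in np.unique(mesh.material):
            nu[mesh.material == lab] = materials[str(lab)][1]
    vm = von_mises_strain(principal[:, 0], principal[:, 1], principal[:, 2], nu)
    return StrainField(regime_id=regime_id, voigt=voigt_ue, principal=principal,
                       von_mises=vm, mode=mode)


# ---------------------------------------------------------------------------
# one full load case


def build_load_vector(mesh: LabeledTetMesh, nodal_forces: dict[int, np.ndarray],
                      ndof: int | None = None) -> np.ndarray:
    f = np.zeros(ndof or 3 * mesh.n_nodes)
    for node, vec in nodal_forces.items():
        f[3 * node : 3 * node + 3] += np.asarray(vec, float)
    return f


def run_load_case(mesh: LabeledTetMesh, materials: MaterialTable, regime,
                  base_system: FESystem | None = None,
                  return_solution: bool = False):
    """Solve one bite loading regime and recover element strains.

    ``regime`` is a :class:`craniostrain.jaw_mda.LoadRegime`.  The strand
    forces load the origin landmark nodes, wrapping paths add link trusses,
    and the regime's bite/TMJ constraint scheme pins six DOFs.
    """
    if base_system is None:
        base_system = attach_surface(assemble_system(mesh, materials), mesh)
    system = base_system
    if regime.wrapping_paths:
        system = add_link_elements(
            system, list(regime.wrapping_paths.values()),
            E_link=materials["link"][0])
        system._surface_ids = base_system._surface_ids

    forces: dict[int, np.ndarray] = {}
    for sid, vec in regime.strand_forces.items():
        node = int(mesh.node_sets[f"origin:{sid}"][0])
        forces[node] = forces.get(node, np.zeros(3)) + np.asarray(vec, float)
    f = build_load_vector(mesh, forces, ndof=system.ndof)

    bite_node = int(mesh.node_sets[f"tooth_tip:{regime.bite_tooth}"][0])
    work = "right" if regime.working_side == "right" else "left"
    bal = "left" if work == "right" else "right"
    scheme = ConstraintScheme.for_bite(
        regime.mode, bite_node,
        int(mesh.node_sets[f"tmj_{work}"][0]),
        int(mesh.node_sets[f"tmj_{bal}"][0]))
    u, reactions = solve_static(system, scheme, f)
    fieldout = element_strains(u[: 3 * mesh.n_nodes], mesh, materials,
                               regime_id=regime.regime_id, mode=regime.mode)
    if return_solution:
        return fieldout, u, reactions, f
    return fieldout
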