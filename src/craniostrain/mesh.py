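"""Labelled tetrahedral mesh container and low-level mesh utilities.

Meshes are linear (4-node) or quadratic (10-node) tetrahedra.  Quadratic
elements follow the VTK node ordering: corners 0-3, then midside nodes on
edges (0,1), (1,2), (0,2), (0,3), (1,4... see ``QUADRATIC_EDGES``.  Corner
ordering is always positively oriented (positive Jacobian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: material labels understood by the default material table
KNOWN_MATERIALS = ("bone", "tooth", "pdl", "pulp", "suture", "link")

#: local corner pairs defining midside nodes of a 10-node tet (VTK order)
QUADRATIC_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))

#: local corner triples of the four faces of a linear tet
TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


class MeshError(ValueError):
    """Raised for structurally invalid meshes or invalid mesh requests."""


@dataclass
class LabeledTetMesh:
    """Tetrahedral mesh with per-element material labels and named node sets.

    Parameters
    ----------
    nodes : (n_nodes, 3) float array
        Node coordinates in mm.
    elements : (n_elem, 4) or (n_elem, 10) int array
        Corner (and midside) node indices, 0-based.
    material : (n_elem,) str array
        One material label per element.
    node_sets : dict[str, int array]
        Named landmark node sets (e.g. ``tmj_left``, ``tooth_tip:incisor_R``).
    """

    nodes: np.ndarray
    elements: np.ndarray
    material: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.material = np.asarray(self.material, dtype="U16")
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise MeshError("elements must be (n, 4) or (n, 10)")
        if len(self.material) != len(self.elements):
            raise MeshError("one material label per element required")
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def order(self) -> int:
        """Element order: 1 for 4-node, 2 for 10-node tetrahedra."""
        return 1 if self.elements.shape[1] == 4 else 2

    def volumes(self) -> np.ndarray:
        """Per-element volume in mm³ (corner-based; edges are straight)."""
        return tet_volumes(self.nodes, self.elements[:, :4])

    def centroids(self) -> np.ndarray:
        """Per-element corner centroid."""
        return self.nodes[self.elements[:, :4]].mean(axis=1)

    def copy(self) -> "LabeledTetMesh":
        return LabeledTetMesh(
            self.nodes.copy(),
            self.elements.copy(),
            self.material.copy(),
            {k: v.copy() for k, v in self.node_sets.items()},
        )

    def find_node(self, xyz, tol: float = 1e-9) -> int:
        """Index of the node at ``xyz`` (within ``tol``), or raise."""
        d = np.abs(self.nodes - np.asarray(xyz, float)).max(axis=1)
        i = int(np.argmin(d))
        if d[i] > tol:
            raise MeshError(f"no node at {tuple(xyz)} (closest {d[i]:.3g} away)")
        return i


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed-turned-positive volumes; raises if any element is inverted."""
    p = nodes[tets]
    v = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0
    if np.any(v <= 0):
        bad = int(np.argmax(v <= 0))
        raise MeshError(f"element {bad} has non-positive volume {v[bad]:.3g}")
    return v


# Kuhn subdivision: the unit cube splits into 6 tets along its main diagonal,
# one per permutation of the axes.  Translated copies of the split are face-
# conforming, so any voxel set meshes conformingly.
_KUHN_PERMS = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))


def _kuhn_local_tets() -> list[tuple[tuple[int, int, int], ...]]:
    tets = []
    for perm in _KUHN_PERMS:
        verts = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in perm:
            cur[ax] += 1
            verts.append(tuple(cur))
        # fix orientation: odd permutations invert the tet
        parity = sum(
            1
            for a in range(3)
            for b in range(a + 1, 3)
            if perm[a] > perm[b]
        )
        if parity % 2 == 1:
            verts[1], verts[2] = verts[2], verts[1]
        tets.append(tuple(verts))
    return tets


_KUHN_TETS = _kuhn_local_tets()


def voxel_mesh(labels: np.ndarray, origin=(0.0, 0.0, 0.0), spacing: float = 1.0) -> LabeledTetMesh:
    """Mesh a labelled voxel grid with 6 Kuhn tetrahedra per occupied voxel.

    Parameters
    ----------
    labels : (nx, ny, nz) object/str array
        Material label per voxel; empty string or None marks void.
    origin : length-3
        Coordinates of the lattice corner of voxel (0, 0, 0).
    spacing : float
        Voxel edge length in mm.

    Unused lattice nodes are compressed out.  Element order groups the six
    tets of each voxel together, voxels in C order.
    """
    labels = np.asarray(labels, dtype=object)
    nx, ny, nz = labels.shape
    occ = np.frompyfunc(lambda l: l is not None and l != "", 1, 1)(labels).astype(bool)
    if not occ.any():
        raise MeshError("no occupied voxels")

    def nid(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    ivox = np.argwhere(occ)
    tets = np.empty((len(ivox) * 6, 4), dtype=np.int64)
    mats = np.empty(len(ivox) * 6, dtype="U16")
    for n, (ix, iy, iz) in enumerate(ivox):
        for t, local in enumerate(_KUHN_TETS):
            tets[6 * n + t] = [nid(ix + dx, iy + dy, iz + dz) for dx, dy, dz in local]
        mats[6 * n : 6 * n + 6] = labels[ix, iy, iz]

    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(tets.shape)
    gx, rem = np.divmod(used, (ny + 1) * (nz + 1))
    gy, gz = np.divmod(rem, nz + 1)
    nodes = np.stack([gx, gy, gz], axis=1).astype(float) * spacing + np.asarray(origin, float)
    return LabeledTetMesh(nodes, tets, mats)


def box_mesh(n: tuple[int, int, int], size: tuple[float, float, float],
             label: str = "bone", origin=(0.0, 0.0, 0.0)) -> LabeledTetMesh:
    """Structured tet mesh of a box: ``n`` cells per axis, ``size`` in mm."""
    nx, ny, nz = n
    if min(n) < 1:
        raise MeshError("cell counts must be >= 1")
    if min(size) <= 0:
        raise MeshError("box dimensions must be positive")
    labels = np.full((nx, ny, nz), label, dtype=object)
    m = voxel_mesh(labels, origin=(0.0, 0.0, 0.0), spacing=1.0)
    m.nodes = m.nodes * (np.asarray(size, float) / np.asarray(n, float)) + np.asarray(origin, float)
    return m


def to_quadratic(mesh: LabeledTetMesh) -> LabeledTetMesh:
    """Convert a linear mesh to 10-node tets by edge-midpoint insertion.

    Midside nodes are shared between elements sharing an edge; they sit at
    the geometric edge midpoint (the phantom geometry is piecewise planar,
    so no snapping to curved boundaries is performed).
    """
    if mesh.order != 1:
        raise MeshError("mesh is already quadratic")
    tets = mesh.elements
    edges = np.concatenate([tets[:, [a, b]] for a, b in QUADRATIC_EDGES], axis=0)
    edges = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid_ids = inv.reshape(len(QUADRATIC_EDGES), len(tets)).T + mesh.n_nodes
    mid_coords = mesh.nodes[uniq].mean(axis=1)
    elements = np.concatenate([tets, mid_ids], axis=1)
    return LabeledTetMesh(
        np.concatenate([mesh.nodes, mid_coords], axis=0),
        elements,
        mesh.material.copy(),
        {k: v.copy() for k, v in mesh.node_sets.items()},
    )


def mirror_mesh(mesh: LabeledTetMesh, tol: float = 1e-9) -> LabeledTetMesh:
    """Append the x→−x mirror image of a linear mesh lying in x ≥ 0.

    Nodes on the plane x = 0 (within ``tol``) are shared between the two
    halves, so the result is conforming.  The mirror partner of element
    ``i`` is element ``i + n_elements``; corner 1 and 2 of each mirrored tet
    are swapped to keep positive orientation.  Node sets are not touched.
    """
    if mesh.order != 1:
        raise MeshError("mirror before quadratic conversion")
    if mesh.nodes[:, 0].min() < -tol:
        raise MeshError("mesh must lie in the half-space x >= 0")
    on_plane = np.abs(mesh.nodes[:, 0]) <= tol
    n = mesh.n_nodes
    new_id = np.empty(n, dtype=np.int64)
    new_id[on_plane] = np.nonzero(on_plane)[0]
    off = np.nonzero(~on_plane)[0]
    new_id[off] = n + np.arange(len(off))
    mirrored_nodes = mesh.nodes[off] * np.array([-1.0, 1.0, 1.0])
    m_tets = new_id[mesh.elements]
    m_tets[:, [1, 2]] = m_tets[:, [2, 1]]
    nodes = np.concatenate([mesh.nodes, mirrored_nodes], axis=0)
    nodes[np.nonzero(on_plane)[0], 0] = 0.0
    return LabeledTetMesh(
        nodes,
        np.concatenate([mesh.elements, m_tets], axis=0),
        np.concatenate([mesh.material, mesh.material]),
        {k: v.copy() for k, v in mesh.node_sets.items()},
    )


def _face_array(mesh: LabeledTetMesh) -> np.ndarray:
    """(4*n_elem, 3) sorted corner-node triples; face f of element e at 4e+f."""
    tets = mesh.elements[:, :4]
    faces = np.concatenate([tets[:, list(f)] for f in TET_FACES], axis=0)
    faces = faces.reshape(4, -1, 3).transpose(1, 0, 2).reshape(-1, 3)
    return np.sort(faces, axis=1)


def boundary_faces(mesh: LabeledTetMesh) -> np.ndarray:
    """Sorted node triples of faces belonging to exactly one element."""
    faces = _face_array(mesh)
    uniq, inv, cnt = np.unique(faces, axis=0, return_inverse=True, return_counts=True)
    if cnt.max() > 2:
        raise MeshError("non-conforming mesh: a face is shared by > 2 elements")
    return uniq[cnt == 1]

def surface_node_ids(mesh: LabeledTetMesh) -> np.ndarray:
    """Ids of nodes lying on the mesh boundary (corner nodes only)."""
    return np.unique(boundary_faces(mesh))


def element_adjacency(mesh: LabeledTetMesh):
    """Pairs (i, j) of elements sharing a face (i < j)."""
    faces = _face_array(mesh)
    order = np.lexsort(faces.T)
    fs = faces[order]
    same = np.all(fs[1:] == fs[:-1], axis=1)
    a = order[:-1][same] // 4
    b = order[1:][same] // 4
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return np.stack([lo, hi], axis=1)


def check_conforming(mesh: LabeledTetMesh) -> None:
    """Raise MeshError if a face is shared by more than two elements."""
    boundary_faces(mesh)
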