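"""Analytic fixture meshes and the parametric synthetic cranium phantom.

The phantom is a deliberately simple stand-in for a lagomorph-like cranium:
a hollow box shell whose lateral walls are fenestrated into discrete struts
in the rostral region, a tooth row per side (one incisor plus a configurable
number of cheek teeth) where each tooth peg carries a pulp core and sits in
a socket lined by a periodontal-ligament (PDL) layer, and a compliant suture
seam crossing the roof.  It exists to exercise every material type, the
fenestration concept and left/right mirror symmetry — not anatomical realism.

Axes: +x mediolateral (mid-sagittal plane at x = 0), +y anteroposterior
(anterior = larger y), +z dorsoventral (dorsal = larger z).  The ventral
shell (palate) spans z in [0, shell_thickness]; teeth hang below z = 0.
All lengths in mm.

Meshes are built by classifying a voxel grid on the x >= 0 half, splitting
each voxel into six Kuhn tetrahedra, and mirroring, so every element has an
exact mirror partner (element ``i + n/2`` for ``i < n/2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from craniostrain.mesh import (
    LabeledTetMesh,
    MeshError,
    box_mesh,
    mirror_mesh,
    to_quadratic,
    voxel_mesh,
)
from craniostrain.mesh_io import read_mesh, write_mesh  # noqa: F401  (module surface)

__all__ = [
    "PhantomParams",
    "phantom_layout",
    "make_unit_cube_mesh",
    "make_cantilever_mesh",
    "make_bimaterial_bar",
    "make_cranium_phantom",
    "material_volumes",
    "read_mesh",
    "write_mesh",
]


# ---------------------------------------------------------------------------
# fixture meshes


def make_unit_cube_mesh(n_per_edge: int, order: int = 1) -> LabeledTetMesh:
    """Conforming tet mesh of the unit cube (1 mm edge), material ``bone``."""
    if order not in (1, 2):
        raise MeshError(f"order must be 1 or 2, got {order}")
    if n_per_edge < 1:
        raise MeshError("n_per_edge must be >= 1")
    m = box_mesh((n_per_edge,) * 3, (1.0, 1.0, 1.0))
    return to_quadratic(m) if order == 2 else m


def make_cantilever_mesh(length: float, depth: float, width: float,
                         n: tuple[int, int, int], order: int = 1) -> LabeledTetMesh:
    """Beam along +x with node sets ``fixed_end`` (x = 0) and ``tip`` (x = L)."""
    if min(length, depth, width) <= 0:
        raise MeshError("beam dimensions must be positive")
    m = box_mesh(n, (length, width, depth))
    if order == 2:
        m = to_quadratic(m)
    x = m.nodes[:, 0]
    tol = 1e-9 * max(length, 1.0)
    m.node_sets["fixed_end"] = np.nonzero(np.abs(x) <= tol)[0]
    m.node_sets["tip"] = np.nonzero(np.abs(x - length) <= tol)[0]
    return m


def make_bimaterial_bar(lengths: tuple[float, float], section: tuple[float, float],
                        n: tuple[int, int, int], labels: tuple[str, str] = ("bone", "tooth"),
                        order: int = 1) -> LabeledTetMesh:
    """Axial bar (along +x) of two materials joined at a conforming plane.

    ``n = (nx_per_half, ny, nz)`` cells; the interface sits at
    ``x = lengths[0]``.
    """
    l1, l2 = lengths
    if min(l1, l2) <= 0 or min(section) <= 0:
        raise MeshError("bar dimensions must be positive")
    if l1 != l2:
        # unequal halves: mesh each with its own axial cell size
        raise MeshError("equal half-lengths required (one structured grid)")
    nx, ny, nz = n
    m = box_mesh((2 * nx, ny, nz), (l1 + l2, section[0], section[1]))
    cx = m.centroids()[:, 0]
    m.material = np.where(cx < l1, labels[0], labels[1]).astype("U16")
    if order == 2:
        m = to_quadratic(m)
    x = m.nodes[:, 0]
    tol = 1e-9 * (l1 + l2)
    m.node_sets["end_a"] = np.nonzero(np.abs(x) <= tol)[0]
    m.node_sets["end_b"] = np.nonzero(np.abs(x - (l1 + l2)) <= tol)[0]
    return m


# ---------------------------------------------------------------------------
# cranium phantom


@dataclass
class PhantomParams:
    """Parameters of the synthetic cranium phantom (all lengths in mm).

    The voxel size is ``cell_size``; every length must be an integer
    multiple of it.  The PDL and suture layers must span at least two
    elements through their thickness so that thin compliant structures are
    resolved, mirroring the meshing rule used for real crania.
    """

    width: float = 24.0          #: overall mediolateral extent
    height: float = 16.0         #: overall dorsoventral extent of the shell
    shell_thickness: float = 2.0
    pdl_thickness: float = 2.0   #: PDL ring thickness around each tooth
    suture_thickness: float = 2.0  #: anteroposterior width of the roof seam
    tooth_length: float = 4.0    #: exposed crown length below the palate
    n_cheek_teeth: int = 5       #: per side, besides the single incisor
    tooth_pitch: float = 8.0     #: anteroposterior spacing of tooth centres
    n_fenestration_struts: int = 4  #: struts per lateral window; 0 = solid wall
    strut_width: float = 2.0
    cell_size: float = 1.0       #: voxel edge length (element size scale)
    order: int = 1               #: 1 = linear, 2 = quadratic tets
    seed: int = 0                #: reserved; construction is deterministic

    def cells(self, value: float, name: str) -> int:
        k = value / self.cell_size
        if abs(k - round(k)) > 1e-9:
            raise MeshError(f"{name}={value} is not a multiple of cell_size={self.cell_size}")
        return int(round(k))

    def validate(self) -> None:
        if self.cell_size <= 0:
            raise MeshError("cell_size must be positive")
        if self.order not in (1, 2):
            raise MeshError("order must be 1 or 2")
        if self.n_cheek_teeth < 1:
            raise MeshError("need at least one cheek tooth")
        if self.pdl_thickness < 2 * self.cell_size - 1e-9:
            raise MeshError("PDL thickness must span >= 2 elements through-thickness")
        if self.suture_thickness < 2 * self.cell_size - 1e-9:
            raise MeshError("suture thickness must span >= 2 elements through-thickness")
        if self.n_fenestration_struts and self.strut_width < self.cell_size - 1e-9:
            raise MeshError("strut width incompatible with element size")
        if self.cells(self.width, "width") % 2:
            raise MeshError("width must be an even number of cells (mirror symmetry)")
        if self.height < 14.0:
            raise MeshError("height must be >= 14 mm (muscle attachment rows)")
        for nm in ("width", "height", "shell_thickness", "pdl_thickness",
                   "suture_thickness", "tooth_length", "tooth_pitch", "strut_width"):
            self.cells(getattr(self, nm), nm)


_MUSCLE_GROUPS = ("masseter", "zygomaticomandibularis", "temporalis",
                  "pterygoid_medial", "pterygoid_lateral")


def phantom_layout(params: PhantomParams) -> dict:
    """Derived phantom layout: overall length, tooth centres, landmark and
    muscle-strand attachment coordinates (right side, in mm).

    The same layout feeds both the mesh builder (landmark node sets) and the
    jaw model (strand origins / via points / insertions), so landmark names
    and geometry stay consistent by construction.
    """
    params.validate()
    hx = params.width / 2.0
    t = params.shell_thickness
    pdl = params.pdl_thickness
    # tooth cross-section: 1 mm pulp column, 1 mm tooth ring, then the PDL ring
    x_lo = hx - t - pdl - 1.0 - 1.0  # lower x of the central pulp column
    cheek = [6.0 + params.tooth_pitch * k for k in range(params.n_cheek_teeth)]
    incisor = cheek[-1] + params.tooth_pitch + 3.0
    length = incisor + 7.0
    w1 = length - 10.0
    w0 = max(22.0, w1 - 20.0)
    tooth_ids = [f"cheek{k + 1}_R" for k in range(params.n_cheek_teeth)] + ["incisor_R"]
    tooth_y = {tid: y for tid, y in zip(tooth_ids, cheek + [incisor])}

    tmj_r = np.array([hx - t - 1.0, 2.0, 0.0])
    tips = {tid: np.array([x_lo, y, -params.tooth_length]) for tid, y in tooth_y.items()}

    strands = []  # (id, group, origin, vias, insertion) right side

    def add(group, k, origin, vias, insertion):
        sid = f"{group}_R_{k:02d}"
        strands.append((sid, group, np.array(origin, float),
                        [np.array(v, float) for v in vias], np.array(insertion, float)))

    k = 0
    for y in (4.0, 8.0, 12.0, 16.0, 20.0):
        for z in (2.0, 4.0, 6.0, 8.0):
            add("masseter", k, (hx, y, z), [], (hx - 2, y + 6, -9.0))
            k += 1
    k = 0
    for y in (6.0, 10.0, 14.0, 18.0, 22.0):
        for z in (10.0, 12.0):
            add("zygomaticomandibularis", k, (hx, y, z), [], (hx - 2, y + 4, -8.0))
            k += 1
    k = 0
    for y in (4.0, 8.0, 12.0, 16.0, 20.0):
        for x in (3.0, 5.0, 7.0, 9.0):
            # superficial temporalis: wraps over the lateral roof edge and
            # down the outer wall before turning to the mandible
            add("temporalis", k, (x, y, params.height),
                [(hx, y, params.height), (hx, y, 10.0)], (hx - 1, y + 2, -6.0))
            k += 1
    k = 0
    for x in (1.0, 2.0):
        for y in ((4.0, 8.0, 12.0, 16.0, 20.0) if x == 1.0 else (6.0, 10.0, 14.0, 18.0, 22.0)):
            add("pterygoid_medial", k, (x, y, 0.0), [], (8.0, y + 6, -10.0))
            k += 1
    k = 0
    for x in (1.0, 2.0, 3.0, 4.0, 5.0):
        # lateral pterygoid: short wrap along the ventral surface to the condyle
        add("pterygoid_lateral", k, (x, 2.0, 0.0), [(x + 2, 2.0, 0.0)],
            (tmj_r[0], 4.0, -2.0))
        k += 1

    return {
        "length": length,
        "half_width": hx,
        "height": params.height,
        "tooth_y": tooth_y,
        "tooth_ids": tooth_ids,
        "tooth_x_lo": x_lo,
        "fenestration_window": (w0, w1),
        "suture_y0": max(4.0, min(length - 6.0, float(int(length) // 2))),
        "tmj_right": tmj_r,
        "tmj_left": tmj_r * np.array([-1.0, 1.0, 1.0]),
        "tooth_tips": tips,
        "strands": strands,
        "muscle_groups": _MUSCLE_GROUPS,
    }


def _classify_half(params: PhantomParams, lay: dict) -> np.ndarray:
    """Voxel labels of the x >= 0 half, shape (hx, L, tooth_len + H) in cells."""
    hx = params.cells(params.width, "width") // 2
    L = params.cells(lay["length"], "length")
    H = params.cells(params.height, "height")
    t = params.cells(params.shell_thickness, "shell_thickness")
    pdl = params.cells(params.pdl_thickness, "pdl_thickness")
    st = params.cells(params.suture_thickness, "suture_thickness")
    tl = params.cells(params.tooth_length, "tooth_length")
    sw = params.cells(params.strut_width, "strut_width")
    x_pulp = params.cells(lay["tooth_x_lo"], "tooth x")
    pu = params.cells(1.0, "pulp width")   # pulp column: 1 mm square
    ring = params.cells(1.0, "tooth ring")  # tooth wall: 1 mm thick
    w0, w1 = (params.cells(v, "window") for v in lay["fenestration_window"])
    sy0 = params.cells(lay["suture_y0"], "suture_y0")
    tooth_rows = sorted(params.cells(y, "tooth y") for y in lay["tooth_y"].values())

    if params.n_fenestration_struts > 1:
        span = (w1 - w0 - sw) / (params.n_fenestration_struts - 1)
        strut_lo = [int(round(w0 + i * span)) for i in range(params.n_fenestration_struts)]
    elif params.n_fenestration_struts == 1:
        strut_lo = [(w0 + w1 - sw) // 2]
    else:
        strut_lo = []

    lab = np.empty((hx, L, H + tl), dtype=object)
    lab[:] = None

    def socket(ix, iy):
        """Material of a socket column at floor level, or None if outside."""
        for cy in tooth_rows:
            dy, dx = iy - cy, ix - x_pulp
            if -ring - pdl <= dx < pu + ring + pdl and -ring - pdl <= dy < pu + ring + pdl:
                if -ring <= dx < pu + ring and -ring <= dy < pu + ring:
                    if 0 <= dx < pu and 0 <= dy < pu:
                        return "pulp"
                    return "tooth"
                return "pdl"
        return None

    for ix in range(hx):
        for iy in range(L):
            for izz in range(H + tl):
                z = izz - tl
                if z < 0:
                    s = socket(ix, iy)
                    if s in ("pulp", "tooth"):
                        # exposed crown: pulp core stops one cell above the tip
                        lab[ix, iy, izz] = "tooth" if (s == "pulp" and z < -tl + 1) else s
                elif z < t:
                    lab[ix, iy, izz] = socket(ix, iy) or "bone"
                elif z >= H - t:
                    lab[ix, iy, izz] = "suture" if sy0 <= iy < sy0 + st else "bone"
                elif ix >= hx - t:
                    if strut_lo and w0 <= iy < w1:
                        if any(s0 <= iy < s0 + sw for s0 in strut_lo):
                            lab[ix, iy, izz] = "bone"
                    elif params.n_fenestration_struts == 0 or not (w0 <= iy < w1):
                        lab[ix, iy, izz] = "bone"
                elif iy < t or iy >= L - t:
                    lab[ix, iy, izz] = "bone"
    return lab


def make_cranium_phantom(params: PhantomParams | None = None) -> LabeledTetMesh:
    """Build the labelled, conforming, mirror-symmetric cranium phantom.

    Node sets: ``tmj_left``, ``tmj_right``, ``tooth_tip:<tooth id>``,
    ``origin:<strand id>`` for every muscle strand on both sides, and
    ``midsagittal_plane``.
    """
    params = params or PhantomParams()
    lay = phantom_layout(params)
    c = params.cell_size
    tl = params.tooth_length
    lab = _classify_half(params, lay)
    half = voxel_mesh(lab, origin=(0.0, 0.0, -tl), spacing=c)
    mesh = mirror_mesh(half)

    def mirr(p):
        return np.asarray(p) * np.array([-1.0, 1.0, 1.0])

    ns = {}
    ns["tmj_right"] = np.array([mesh.find_node(lay["tmj_right"])])
    ns["tmj_left"] = np.array([mesh.find_node(lay["tmj_left"])])
    for tid, tip in lay["tooth_tips"].items():
        ns[f"tooth_tip:{tid}"] = np.array([mesh.find_node(tip)])
        ns[f"tooth_tip:{tid[:-2]}_L"] = np.array([mesh.find_node(mirr(tip))])
    for sid, _grp, origin, _vias, _ins in lay["strands"]:
        ns[f"origin:{sid}"] = np.array([mesh.find_node(origin)])
        lid = sid.replace("_R_", "_L_")
        ns[f"origin:{lid}"] = np.array([mesh.find_node(mirr(origin))])
    ns["midsagittal_plane"] = np.nonzero(np.abs(mesh.nodes[:, 0]) <= 1e-9)[0]
    mesh.node_sets = ns

    if params.order == 2:
        mesh = to_quadratic(mesh)
    return mesh


def material_volumes(mesh: LabeledTetMesh) -> dict[str, float]:
    """Total element volume (mm³) per material label."""
    v = mesh.volumes()
    return {str(lab): float(v[mesh.material == lab].sum()) for lab in np.unique(mesh.material)}
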