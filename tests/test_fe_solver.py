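"""Element stiffness, solves, strain recovery and link elements.

The assembly oracle here recomputes element matrices independently:
shape-function gradients by central finite differences on the reference
element, mapped through the element Jacobian, integrated with the same
4-point rule — no code shared with the vectorized production path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craniostrain.fe_solver import (
    ConstraintScheme,
    MaterialTable,
    SingularSystemError,
    add_link_elements,
    assemble_system,
    attach_surface,
    element_strains,
    run_load_case,
    solve_static,
    von_mises_strain,
)
from craniostrain.mesh import LabeledTetMesh, MeshError, QUADRATIC_EDGES
from craniostrain.phantom_geometry import (
    make_bimaterial_bar,
    make_cantilever_mesh,
    make_unit_cube_mesh,
)


# ---------------------------------------------------------------------------
# independent dense assembly oracle


def _shape_funcs(order):
    def lam(xi):
        return np.array([1 - xi.sum(), xi[0], xi[1], xi[2]])

    if order == 1:
        return lambda xi: lam(xi)

    def N(xi):
        l = lam(xi)
        out = np.empty(10)
        out[:4] = l * (2 * l - 1)
        for k, (a, b) in enumerate(QUADRATIC_EDGES):
            out[4 + k] = 4 * l[a] * l[b]
        return out

    return N


def _oracle_stiffness(mesh, materials):
    """Dense global stiffness by naive per-element loops and FD gradients."""
    order = mesh.order
    N = _shape_funcs(order)
    nn = 4 if order == 1 else 10
    ga, gb = 0.5854101966249685, 0.13819660112501052
    pts = [np.array([gb, gb, gb]), np.array([ga, gb, gb]),
           np.array([gb, ga, gb]), np.array([gb, gb, ga])]
    if order == 1:
        pts = [np.array([0.25, 0.25, 0.25])]
    ndof = 3 * mesh.n_nodes
    K = np.zeros((ndof, ndof))
    h = 1e-6
    for e in range(mesh.n_elements):
        conn = mesh.elements[e]
        X = mesh.nodes[conn]
        E, nu = materials[str(mesh.material[e])]
        lamc = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lamc
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[3:, 3:] = np.eye(3) * mu
        Ke = np.zeros((3 * nn, 3 * nn))
        for xi in pts:
            dN = np.zeros((nn, 3))
            for d in range(3):
                e1 = np.zeros(3)
                e1[d] = h
                dN[:, d] = (N(xi + e1) - N(xi - e1)) / (2 * h)
            J = dN.T @ X            # dx/dxi
            detJ = np.linalg.det(J)
            G = dN @ np.linalg.inv(J).T  # dN/dx
            B = np.zeros((6, 3 * nn))
            for a in range(nn):
                gx, gy, gz = G[a]
                B[0, 3 * a] = gx
                B[1, 3 * a + 1] = gy
                B[2, 3 * a + 2] = gz
                B[3, 3 * a], B[3, 3 * a + 1] = gy, gx
                B[4, 3 * a + 1], B[4, 3 * a + 2] = gz, gy
                B[5, 3 * a], B[5, 3 * a + 2] = gz, gx
            Ke += (detJ / 6.0) / len(pts) * B.T @ D @ B
        dofs = np.concatenate([[3 * c, 3 * c + 1, 3 * c + 2] for c in conn])
        K[np.ix_(dofs, dofs)] += Ke
    return K


@pytest.mark.parametrize("order", [1, 2])
def test_assembly_matches_dense_oracle(order, rng, materials):
    mesh = make_unit_cube_mesh(1, order=1)
    # jitter corner nodes (keeps positive volumes at this amplitude)
    mesh.nodes += rng.uniform(-0.05, 0.05, mesh.nodes.shape)
    mesh.material[:] = ["bone", "pdl", "tooth", "suture", "pulp", "bone"][: mesh.n_elements]
    if order == 2:
        from craniostrain.mesh import to_quadratic

        mesh = to_quadratic(mesh)
    K = assemble_system(mesh, materials).K.toarray()
    K_ref = _oracle_stiffness(mesh, materials)
    scale = np.abs(K_ref).max()
    assert np.abs(K - K_ref).max() < 1e-6 * scale


def test_single_tet_block_symmetric(materials):
    mesh = LabeledTetMesh(
        nodes=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
        elements=np.array([[0, 1, 2, 3]]),
        material=np.array(["bone"]))
    K = assemble_system(mesh, materials).K.toarray()
    assert K.shape == (12, 12)
    assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()


def test_rigid_body_modes_have_zero_energy(materials):
    mesh = make_unit_cube_mesh(2)
    K = assemble_system(mesh, materials).K
    n = mesh.n_nodes
    modes = []
    for d in range(3):  # translations
        u = np.zeros((n, 3))
        u[:, d] = 1.0
        modes.append(u.ravel())
    c = mesh.nodes - mesh.nodes.mean(axis=0)
    for ax in range(3):  # linearized rotations
        w = np.zeros(3)
        w[ax] = 1.0
        modes.append(np.cross(w, c).ravel())
    scale = np.abs(K.data).max()
    for u in modes:
        assert np.abs(K @ u).max() < 1e-9 * scale
    # six and only six: the 7th smallest eigenvalue is well above zero
    vals = np.linalg.eigvalsh(K.toarray())
    assert np.all(np.abs(vals[:6]) < 1e-6 * scale)
    assert vals[6] > 1e-6 * scale


def _uniaxial_patch(mesh, materials, strain=1e-3):
    entries = []
    L = mesh.nodes[:, 0].max()
    for i, p in enumerate(mesh.nodes):
        if abs(p[0]) < 1e-12:
            entries.append((i, 0, 0.0))
        if abs(p[0] - L) < 1e-12:
            entries.append((i, 0, strain * L))
    o = int(np.argmin(np.abs(mesh.nodes).sum(axis=1)))
    entries += [(o, 1, 0.0), (o, 2, 0.0)]
    ey = int(np.argmin(np.abs(mesh.nodes - [0, mesh.nodes[:, 1].max(), 0]).sum(axis=1)))
    ez = int(np.argmin(np.abs(mesh.nodes - [0, 0, mesh.nodes[:, 2].max()]).sum(axis=1)))
    entries += [(ey, 2, 0.0), (ez, 1, 0.0)]
    sys_ = assemble_system(mesh, materials)
    return solve_static(sys_, ConstraintScheme(entries=entries), np.zeros(sys_.ndof))


@pytest.mark.parametrize("order", [1, 2])
def test_patch_test_uniform_uniaxial_strain(order, materials):
    """Prescribed end displacements producing 1000 µε stretch give a uniform
    strain field with principal strains (1000, -300, -300) µε for ν = 0.3."""
    mesh = make_unit_cube_mesh(2, order=order)
    u, _ = _uniaxial_patch(mesh, materials)
    f = element_strains(u, mesh, materials)
    assert np.allclose(f.voigt[:, 0], 1000.0, atol=1e-6)
    assert np.allclose(f.principal, [1000.0, -300.0, -300.0], atol=1e-6)
    assert np.allclose(f.von_mises, 1000.0, atol=1e-6)


def test_cantilever_converges_to_euler_bernoulli(materials):
    """Tip deflection approaches P L^3 / 3EI monotonically from below and is
    within 5 % at the finest refinement (quadratic tets)."""
    E, _ = materials["bone"]
    L, d, w, P = 20.0, 1.0, 1.0, 1.0
    I = w * d**3 / 12
    exact = P * L**3 / (3 * E * I)
    errors = []
    for n in [(4, 1, 1), (8, 1, 1), (14, 2, 2)]:
        mesh = make_cantilever_mesh(L, d, w, n, order=2)
        sys_ = assemble_system(mesh, materials)
        entries = [(int(i), a, 0.0) for i in mesh.node_sets["fixed_end"] for a in range(3)]
        tips = mesh.node_sets["tip"]
        f = np.zeros(sys_.ndof)
        f[3 * tips + 2] = P / len(tips)
        u, _ = solve_static(sys_, ConstraintScheme(entries=entries), f)
        defl = u[3 * tips + 2].mean()
        errors.append(abs(defl / exact - 1))
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 0.05


def test_bimaterial_bar_strain_ratio_inverse_of_stiffness(materials):
    """A 2:1 stiffness ratio under axial load produces 1:2 strains; a 1:1
    bar recovers the single-material uniform state."""
    mats = MaterialTable({"bone": (200.0, 0.3), "tooth": (100.0, 0.3),
                          "pdl": (50, 0.49), "suture": (20, 0.49),
                          "pulp": (2, 0.49), "link": (200, 0.3)})
    mesh = make_bimaterial_bar((5.0, 5.0), (1.0, 1.0), (5, 2, 2))
    sys_ = assemble_system(mesh, mats)
    entries = [(int(i), 0, 0.0) for i in mesh.node_sets["end_a"]]
    o = mesh.find_node((0, 0, 0))
    entries += [(o, 1, 0.0), (o, 2, 0.0),
                (mesh.find_node((0, 1, 0)), 2, 0.0), (mesh.find_node((0, 0, 1)), 1, 0.0)]
    f = np.zeros(sys_.ndof)
    ids = mesh.node_sets["end_b"]
    f[3 * ids] = 1.0 / len(ids)
    u, _ = solve_static(sys_, ConstraintScheme(entries=entries), f)
    strains = element_strains(u, mesh, mats)
    cx = mesh.centroids()[:, 0]
    mid_stiff = strains.voigt[(cx > 1) & (cx < 4), 0].mean()
    mid_soft = strains.voigt[(cx > 6) & (cx < 9), 0].mean()
    assert mid_soft / mid_stiff == pytest.approx(2.0, rel=0.02)

    # identity case: equal stiffness -> both halves carry identical strain,
    # indistinguishable from a single-material bar
    mats_eq = MaterialTable({**mats.materials, "tooth": (200.0, 0.3)})
    sys_eq = assemble_system(mesh, mats_eq)
    u2, _ = solve_static(sys_eq, ConstraintScheme(entries=entries), f)
    s2 = element_strains(u2, mesh, mats_eq)
    m_stiff = s2.voigt[(cx > 1) & (cx < 4), 0].mean()
    m_soft = s2.voigt[(cx > 6) & (cx < 9), 0].mean()
    assert m_soft / m_stiff == pytest.approx(1.0, rel=0.01)


def test_global_equilibrium_reactions_balance_loads(materials, rng):
    mesh = make_unit_cube_mesh(2)
    sys_ = assemble_system(mesh, materials)
    fixed_nodes = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-12)
    entries = [(int(i), a, 0.0) for i in fixed_nodes for a in range(3)]
    f = rng.normal(size=sys_.ndof) * 0.5
    for i, a, _ in entries:
        f[3 * i + a] = 0.0
    u, r = solve_static(sys_, ConstraintScheme(entries=entries), f)
    total = f.reshape(-1, 3).sum(axis=0) + r.reshape(-1, 3).sum(axis=0)
    assert np.abs(total).max() < 1e-6 * max(1.0, np.abs(f).max())


def test_linearity_and_superposition(materials, rng):
    mesh = make_unit_cube_mesh(2)
    sys_ = assemble_system(mesh, materials)
    fixed = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-12)
    scheme = ConstraintScheme(entries=[(int(i), a, 0.0) for i in fixed for a in range(3)])
    f1 = rng.normal(size=sys_.ndof)
    f2 = rng.normal(size=sys_.ndof)
    u1, _ = solve_static(sys_, scheme, f1)
    u2, _ = solve_static(sys_, scheme, f2)
    u12, _ = solve_static(sys_, scheme, f1 + f2)
    u1x2, _ = solve_static(sys_, scheme, 2 * f1)
    assert np.allclose(u12, u1 + u2, atol=1e-10 * max(1, np.abs(u1).max()))
    assert np.allclose(u1x2, 2 * u1, atol=1e-12)
    # zero loads -> zero strains
    u0, _ = solve_static(sys_, scheme, np.zeros(sys_.ndof))
    assert np.abs(element_strains(u0, mesh, materials).von_mises).max() == 0.0


def test_underconstrained_system_reported(materials):
    mesh = make_unit_cube_mesh(1)
    sys_ = assemble_system(mesh, materials)
    scheme = ConstraintScheme(entries=[(0, 0, 0.0)])  # rigid modes remain
    f = np.zeros(sys_.ndof)
    f[-1] = 1.0
    with pytest.raises(SingularSystemError):
        solve_static(sys_, scheme, f)


class TestStrainRecovery:
    def test_rigid_rotation_produces_no_strain(self, materials):
        mesh = make_unit_cube_mesh(2)
        ang = 1e-5  # small-rotation linearization
        c = mesh.nodes - 0.5
        u = np.cross([0, 0, ang], c).ravel()
        f = element_strains(u, mesh, materials)
        assert np.abs(f.von_mises).max() < 1e-4  # µε; O(ang² * 1e6)

    def test_principal_strains_match_characteristic_roots(self, rng):
        for _ in range(20):
            t = rng.normal(size=(3, 3))
            t = (t + t.T) / 2
            ours = np.sort(np.linalg.eigvalsh(t))[::-1]
            # independent oracle: roots of the characteristic polynomial
            c2 = -np.trace(t)
            c1 = 0.5 * (np.trace(t) ** 2 - np.trace(t @ t))
            c0 = -np.linalg.det(t)
            roots = np.sort(np.roots([1.0, c2, c1, c0]).real)[::-1]
            assert np.allclose(ours, roots, atol=1e-8)


class TestVonMises:
    def test_uniaxial_recovers_axial_strain(self):
        assert von_mises_strain(1000.0, -300.0, -300.0, 0.3) == pytest.approx(1000.0)

    def test_hydrostatic_gives_zero(self):
        assert von_mises_strain(123.0, 123.0, 123.0, 0.49) == 0.0

    @given(st.permutations([250.0, -100.0, 40.0]))
    @settings(max_examples=6, deadline=None)
    def test_permutation_invariance(self, perm):
        ref = von_mises_strain(250.0, -100.0, 40.0, 0.3)
        assert von_mises_strain(*perm, 0.3) == pytest.approx(ref, rel=1e-12)


class TestLinkElements:
    def _bar_system(self, materials):
        mesh = make_cantilever_mesh(10.0, 2.0, 2.0, (5, 2, 2))
        sys_ = attach_surface(assemble_system(mesh, materials), mesh)
        return mesh, sys_

    def test_straight_chain_transmits_axial_force(self, materials):
        """An axial pull on the free end of a surface truss chain reaches the
        anchors: the constrained mesh reacts with the full applied load."""
        mesh, sys_ = self._bar_system(materials)
        top = mesh.nodes[:, 2].max()
        path = np.array([[2.0, 0.0, top], [5.0, 0.0, top], [8.0, 0.0, top]])
        aug = add_link_elements(sys_, [path])
        fixed = mesh.node_sets["fixed_end"]
        scheme = ConstraintScheme(entries=[(int(i), a, 0.0) for i in fixed for a in range(3)])
        f = np.zeros(aug.ndof)
        end = mesh.find_node([8.0, 0.0, top])
        f[3 * end] = 5.0  # axial (+x) pull at the chain end node
        u, r = solve_static(aug, scheme, f)
        assert r.reshape(-1, 3)[:, 0].sum() == pytest.approx(-5.0, abs=1e-8)

    def test_floating_joint_anchored_perpendicular(self, materials):
        """A path joint hovering above the surface gets its own node plus an
        anchor truss; axial stiffness through the anchor far exceeds the
        weak-spring transverse stiffness (trusses carry no bending)."""
        mesh, sys_ = self._bar_system(materials)
        top = mesh.nodes[:, 2].max()
        joint = np.array([5.0, 1.0, top + 0.5])  # 0.5 mm above a surface node
        path = np.array([[2.0, 1.0, top], joint, [8.0, 1.0, top]])
        aug = add_link_elements(sys_, [path])
        assert aug.coords.shape[0] == mesh.n_nodes + 1
        jid = mesh.n_nodes
        fixed = mesh.node_sets["fixed_end"]
        scheme = ConstraintScheme(entries=[(int(i), a, 0.0) for i in fixed for a in range(3)])
        # load along the anchor axis (z) vs transverse to chain+anchor (y)
        fz = np.zeros(aug.ndof)
        fz[3 * jid + 2] = 1.0
        uz, _ = solve_static(aug, scheme, fz)
        fy = np.zeros(aug.ndof)
        fy[3 * jid + 1] = 1.0
        uy, _ = solve_static(aug, scheme, fy)
        assert abs(uy[3 * jid + 1]) > 100 * abs(uz[3 * jid + 2])

    def test_zero_length_segment_rejected(self, materials):
        mesh, sys_ = self._bar_system(materials)
        top = mesh.nodes[:, 2].max()
        path = np.array([[2.0, 0.0, top], [2.0, 0.0, top]])
        with pytest.raises(MeshError):
            add_link_elements(sys_, [path])

    def test_path_point_off_surface_rejected(self, materials):
        mesh, sys_ = self._bar_system(materials)
        path = np.array([[2.0, 0.0, 50.0], [8.0, 0.0, 50.0]])  # far away
        with pytest.raises(MeshError):
            add_link_elements(sys_, [path])


class TestRegimeSolutions:
    def test_mirrored_regime_gives_mirrored_strains(self, pipeline_run, phantom_small):
        """Per-element von Mises strain of a left bite equals its mirror
        partner's under the matching right bite, within 0.1 %."""
        _, report = pipeline_run
        by_id = {f.regime_id: f for f in report.fields}
        right = by_id["molar_cheek1_R"]
        left = by_id["molar_cheek1_L"]
        # mirror partner map, recovered independently from centroids
        from scipy.spatial import cKDTree

        c = phantom_small.centroids()
        mirrored = c * np.array([-1.0, 1.0, 1.0])
        _, partner = cKDTree(c).query(mirrored)
        assert np.array_equal(partner[partner], np.arange(len(c)))  # involution
        vm_r = right.von_mises
        vm_l = left.von_mises[partner]
        scale = vm_r.max()
        assert np.abs(vm_r - vm_l).max() <= 1e-3 * scale

    def test_scaled_loads_scale_strains(self, phantom_small, materials, pipeline_run):
        import json
        from pathlib import Path

        from craniostrain.pipeline_cli import regime_from_json

        cfg, _report = pipeline_run
        regs = json.loads((Path(cfg.output_dir) / "regimes.json").read_text())
        reg = regime_from_json(regs[2])
        f1 = run_load_case(phantom_small, materials, reg)
        reg2 = regime_from_json(regs[2])
        reg2.strand_forces = {k: 2 * np.asarray(v) for k, v in reg2.strand_forces.items()}
        f2 = run_load_case(phantom_small, materials, reg2)
        assert np.allclose(f2.von_mises, 2 * f1.von_mises, rtol=1e-9, atol=1e-9)
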