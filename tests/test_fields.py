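import logging

import numpy as np
import pytest

from qrscale import (
    BULK,
    ENDO_LAYER,
    ConductionParams,
    EllipsoidParams,
    SurfaceLabel,
    TetMesh,
    assign_fibers,
    build_conduction,
    helix_angles,
    make_box,
    make_ellipsoid_lv,
    solve_laplace,
    solve_laplace_labels,
    tag_endo_layer,
    ventricular_coords,
)
from qrscale.fields import FrameConstructionError

from oracles import signed_wall_depth, voxel_endo_layer_fraction


# ---------------------------------------------------------------------------
# Laplace solves


def test_laplace_linear_along_bar():
    bar = make_box((20.0, 2.0, 2.0), 1.0)  # ENDO at x=0, EPI at x=20
    u = solve_laplace_labels(bar, {SurfaceLabel.ENDO: 0.0, SurfaceLabel.EPI: 1.0})
    assert np.abs(u - bar.nodes[:, 0] / 20.0).max() < 1e-6


def test_laplace_spherical_shell_profile():
    """Hemispherical shell r in [22, 42]: harmonic radial profile (1/r - 1/r1)/(1/r2 - 1/r1).

    The flat equatorial base is natural (zero-flux), which matches the
    symmetry plane of the full-shell solution.
    """
    p = EllipsoidParams((22.0, 22.0, 22.0), 20.0, 1.0, 2.0)
    shell = make_ellipsoid_lv(p)
    u = solve_laplace_labels(shell, {SurfaceLabel.ENDO: 0.0, SurfaceLabel.EPI: 1.0})
    r = np.linalg.norm(shell.nodes, axis=1)
    exact = (1.0 / r - 1.0 / 22.0) / (1.0 / 42.0 - 1.0 / 22.0)
    assert np.abs(u - exact).max() < 0.02


def test_laplace_constant_boundary_gives_constant_field(lv_mesh):
    u = solve_laplace_labels(
        lv_mesh, {SurfaceLabel.ENDO: 0.7, SurfaceLabel.EPI: 0.7, SurfaceLabel.BASE: 0.7}
    )
    assert np.abs(u - 0.7).max() < 1e-10


def test_laplace_requires_dirichlet(lv_mesh):
    with pytest.raises(ValueError):
        solve_laplace(lv_mesh, {})


# ---------------------------------------------------------------------------
# ventricular coordinates


def test_transmural_matches_wall_depth_oracle(lv_mesh, lv_model):
    depth = signed_wall_depth(lv_mesh.nodes, 20.0, 20.0, 60.0, 10.0)
    # away from the basal edge, where the Neumann condition bends the field
    interior = lv_mesh.nodes[:, 2] < -10.0
    assert np.abs(lv_model.coords.transmural[interior] - depth[interior]).max() < 0.05


def test_coordinate_boundary_values_exact(lv_mesh, lv_model):
    c = lv_model.coords
    endo = lv_mesh.nodes_with_label(SurfaceLabel.ENDO)
    epi = lv_mesh.nodes_with_label(SurfaceLabel.EPI)
    base = lv_mesh.nodes_with_label(SurfaceLabel.BASE)
    assert np.abs(c.transmural[endo]).max() == 0.0
    assert np.abs(c.transmural[epi] - 1.0).max() == 0.0
    assert np.abs(c.apicobasal[base] - 1.0).max() == 0.0
    assert c.apicobasal[c.apex_node] == 0.0
    interior = np.setdiff1d(np.arange(lv_mesh.n_nodes), np.unique(lv_mesh.boundary_faces))
    assert (c.transmural[interior] > 0).all() and (c.transmural[interior] < 1).all()
    assert (c.apicobasal[interior] > 0).all() and (c.apicobasal[interior] < 1).all()


def test_apicobasal_tracks_arc_length(lv_mesh, lv_model):
    """The renormalized apicobasal coordinate is ~monotone in distance-from-base
    and spreads over [0,1] rather than clustering at 1."""
    ab = lv_model.coords.apicobasal
    assert 0.15 < np.mean(ab < 1.0 / 3.0) < 0.55


# ---------------------------------------------------------------------------
# fibers


def test_helix_angle_rule_endo_to_epi(lv_mesh, lv_model):
    """Helix angle is +40 deg at the endocardium, -50 deg at the epicardium,
    linear in transmural depth (zero crossing at d = 40/90)."""
    ha = helix_angles(lv_mesh, lv_model.coords, lv_model.fibers)
    d = lv_model.coords.transmural[lv_mesh.tets].mean(axis=1)
    expected = 40.0 * (1.0 - d) - 50.0 * d
    assert np.abs(ha - expected).max() < 1.0
    # linearity: regression slope over a transmural sample
    slope = np.polyfit(d, ha, 1)[0]
    assert slope == pytest.approx(-90.0, abs=2.0)
    near_zero = np.abs(d - 40.0 / 90.0) < 0.02
    if near_zero.any():
        assert np.abs(ha[near_zero]).max() < 1.0 + 90.0 * 0.02


def test_fiber_frames_orthonormal_and_continuous(lv_mesh, lv_model):
    f, t1, t2 = lv_model.fibers.f, lv_model.fibers.t1, lv_model.fibers.t2
    for a, b in [(f, f), (t1, t1), (t2, t2)]:
        assert np.abs(np.einsum("md,md->m", a, b) - 1).max() < 1e-6
    for a, b in [(f, t1), (f, t2), (t1, t2)]:
        assert np.abs(np.einsum("md,md->m", a, b)).max() < 1e-6
    # continuity: fiber angle jump across face-adjacent tets < 30 deg
    faces = lv_mesh.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    tet_of = np.repeat(np.arange(lv_mesh.n_tets), 4)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    ks, ts = key[order], tet_of[order]
    same = (ks[1:] == ks[:-1]).all(axis=1)
    a, b = ts[:-1][same], ts[1:][same]
    cosang = np.clip(np.abs(np.einsum("md,md->m", f[a], f[b])), 0, 1)
    assert np.rad2deg(np.arccos(cosang)).max() < 30.0


def test_fiber_frames_rotation_equivariant(coarse_lv_model):
    mesh = coarse_lv_model.mesh
    rng = np.random.default_rng(5)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    rot = TetMesh(
        nodes=mesh.nodes @ q.T, tets=mesh.tets,
        boundary_faces=mesh.boundary_faces, boundary_labels=mesh.boundary_labels,
    )
    coords_r = ventricular_coords(rot)
    fib_r = assign_fibers(rot, coords_r)
    assert np.abs(fib_r.f - coarse_lv_model.fibers.f @ q.T).max() < 1e-6


def test_degenerate_gradient_raises():
    bar = make_box((4.0, 2.0, 2.0), 2.0)
    from qrscale.fields import VentricularCoords

    flat = VentricularCoords(
        transmural=np.zeros(bar.n_nodes), apicobasal=np.zeros(bar.n_nodes), apex_node=0
    )
    with pytest.raises(FrameConstructionError):
        assign_fibers(bar, flat)


# ---------------------------------------------------------------------------
# endocardial layer


def test_endo_layer_volume_fraction_vs_voxel_oracle(lv_mesh):
    tags = tag_endo_layer(lv_mesh, 1.0)
    vols = lv_mesh.tet_volumes()
    frac = vols[tags == ENDO_LAYER].sum() / vols.sum()
    oracle = voxel_endo_layer_fraction(20, 20, 60, 10, 0.0, thickness=1.0, pitch=0.5)
    assert frac == pytest.approx(oracle, rel=0.15)


def test_endo_layer_degenerate_thicknesses(lv_mesh, caplog):
    with caplog.at_level(logging.WARNING, logger="qrscale"):
        tags0 = tag_endo_layer(lv_mesh, 0.0)
    assert (tags0 == BULK).all()
    assert caplog.records
    caplog.clear()
    with caplog.at_level(logging.WARNING, logger="qrscale"):
        tags_all = tag_endo_layer(lv_mesh, 100.0)
    assert (tags_all == ENDO_LAYER).all()
    assert caplog.records


# ---------------------------------------------------------------------------
# conduction tensors


def _flat_field(mesh):
    f = np.zeros((mesh.n_tets, 3))
    f[:, 0] = 1.0
    t1 = np.zeros((mesh.n_tets, 3))
    t1[:, 1] = 1.0
    t2 = np.zeros((mesh.n_tets, 3))
    t2[:, 2] = 1.0
    from qrscale.fields import FiberField

    return FiberField(f=f, t1=t1, t2=t2)


def test_conduction_eigenvalues_bulk_and_layer():
    mesh = make_box((4.0, 4.0, 4.0), 2.0)
    fib = _flat_field(mesh)
    tags = np.zeros(mesh.n_tets, dtype=np.int64)
    tags[0] = ENDO_LAYER
    model = build_conduction(mesh, fib, tags, ConductionParams(cv_long=0.5))
    ev_bulk = np.sort(np.linalg.eigvalsh(model.tensors[1]))
    assert ev_bulk == pytest.approx([0.04, 0.04, 0.25], rel=1e-12)
    ev_layer = np.sort(np.linalg.eigvalsh(model.tensors[0]))
    assert ev_layer == pytest.approx(36.0 * ev_bulk, rel=1e-12)


def test_conduction_isotropic_limit():
    mesh = make_box((4.0, 4.0, 4.0), 2.0)
    model = build_conduction(
        mesh, _flat_field(mesh), np.zeros(mesh.n_tets, dtype=np.int64),
        ConductionParams(cv_long=2.0, anisotropy_ratio=1.0),
    )
    assert np.abs(model.tensors - 4.0 * np.eye(3)).max() < 1e-12


def test_conduction_speed_scaling_quadratic():
    mesh = make_box((4.0, 4.0, 4.0), 2.0)
    tags = np.zeros(mesh.n_tets, dtype=np.int64)
    m1 = build_conduction(mesh, _flat_field(mesh), tags, ConductionParams(cv_long=0.5))
    m3 = build_conduction(mesh, _flat_field(mesh), tags, ConductionParams(cv_long=1.5))
    assert np.abs(m3.tensors - 9.0 * m1.tensors).max() < 1e-12
    assert (m3.region == m1.region).all()


def test_conduction_longitudinal_speedup_mode():
    mesh = make_box((4.0, 4.0, 4.0), 2.0)
    tags = np.full(mesh.n_tets, ENDO_LAYER, dtype=np.int64)
    model = build_conduction(
        mesh, _flat_field(mesh), tags,
        ConductionParams(cv_long=0.5, speedup_mode="longitudinal"),
    )
    ev = np.sort(np.linalg.eigvalsh(model.tensors[0]))
    assert ev == pytest.approx([0.04, 0.04, 9.0], rel=1e-12)


def test_conduction_rejects_non_unit_fibers():
    mesh = make_box((4.0, 4.0, 4.0), 2.0)
    fib = _flat_field(mesh)
    from qrscale.fields import FiberField

    bad = FiberField(f=fib.f * 2.0, t1=fib.t1, t2=fib.t2)
    with pytest.raises(ValueError):
        build_conduction(mesh, bad, np.zeros(mesh.n_tets, dtype=np.int64), ConductionParams(1.0))
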