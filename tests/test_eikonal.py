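import numpy as np
import pytest
from scipy.spatial import Delaunay

from qrscale import (
    ConductionModel,
    ConductionParams,
    EllipsoidParams,
    StimulusSet,
    TetMesh,
    UnreachableNodesError,
    dijkstra_oracle,
    make_box,
    make_ellipsoid_lv,
    solve_eikonal,
    total_activation_time,
)

from conftest import axis_aligned_conduction


def jittered_delaunay_mesh(rng, n_side=8, jitter=0.35, size=20.0):
    """Random-but-non-degenerate tet mesh: Delaunay of a jittered grid."""
    g = np.linspace(0, size, n_side)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    h = size / (n_side - 1)
    pts = pts + rng.uniform(-jitter * h, jitter * h, pts.shape)
    tets = Delaunay(pts).simplices
    a = pts[tets[:, 1]] - pts[tets[:, 0]]
    b = pts[tets[:, 2]] - pts[tets[:, 0]]
    c = pts[tets[:, 3]] - pts[tets[:, 0]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    return TetMesh.create(pts, tets[np.abs(vol) > 1e-9], validate=False)


def random_spd_tensors(rng, m, ratio_range=(0.3, 1.0)):
    """Random orientations with transversely isotropic physiological anisotropy."""
    T = np.empty((m, 3, 3))
    for i in range(m):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        r = rng.uniform(*ratio_range)
        T[i] = q @ np.diag([1.0, r * r, r * r]) @ q.T
    return T


def test_isotropic_slab_matches_distance(iso_slab):
    """Unit speed (1 mm/ms): arrival time equals Euclidean distance within 2%."""
    mesh, model, src = iso_slab
    amap = solve_eikonal(mesh, model, StimulusSet(np.array([src])))
    d = np.linalg.norm(mesh.nodes - mesh.nodes[src], axis=1)
    far = d > 2.0
    rel = np.abs(amap.times[far] - d[far]) / d[far]
    assert rel.max() < 0.02
    assert amap.times[src] == 0.0


def test_anisotropic_principal_axis_arrivals():
    """Fiber along +x, v_f=1, v_t=0.4: t(10,0,0)=10 ms, t(0,10,0)=25 ms within 3%."""
    mesh = make_box((12.0, 12.0, 3.0), 1.0)
    model = axis_aligned_conduction(mesh)
    src = int(np.argmin(np.linalg.norm(mesh.nodes, axis=1)))
    amap = solve_eikonal(mesh, model, StimulusSet(np.array([src])))
    ix = int(np.argmin(np.linalg.norm(mesh.nodes - [10, 0, 0], axis=1)))
    iy = int(np.argmin(np.linalg.norm(mesh.nodes - [0, 10, 0], axis=1)))
    assert amap.times[ix] == pytest.approx(10.0, rel=0.03)
    assert amap.times[iy] == pytest.approx(25.0, rel=0.03)


def test_oracle_matches_on_bar_along_fiber():
    """Straight bar, fiber axial: shortest paths run along edges, so the graph
    oracle and the eikonal solve agree within 1%."""
    bar = make_box((30.0, 2.0, 2.0), 1.0)
    model = axis_aligned_conduction(bar)
    src = int(np.argmin(np.linalg.norm(bar.nodes, axis=1)))
    am = solve_eikonal(bar, model, StimulusSet(np.array([src])))
    do = dijkstra_oracle(bar, model, StimulusSet(np.array([src])))
    # along the bar axis the shortest path runs down mesh edges
    axis = (bar.nodes[:, 1] == 0) & (bar.nodes[:, 2] == 0) & (am.times > 2.0)
    assert (np.abs(do.times[axis] - am.times[axis]) / am.times[axis]).max() < 0.01


def test_oracle_upper_bounds_eikonal_on_sphere_shell():
    """Point stimulus on an isotropic spherical shell: the graph-restricted
    oracle lies above the eikonal solution everywhere."""
    p = EllipsoidParams((22.0, 22.0, 22.0), 20.0, 1.0, 2.5)
    shell = make_ellipsoid_lv(p)
    tensors = np.tile(np.eye(3), (shell.n_tets, 1, 1))
    model = ConductionModel(
        tensors=tensors, region=np.zeros(shell.n_tets, dtype=np.int64),
        params=ConductionParams(1.0),
    )
    src = int(np.argmin(np.linalg.norm(shell.nodes - [0, 0, -42.0], axis=1)))
    am = solve_eikonal(shell, model, StimulusSet(np.array([src])))
    do = dijkstra_oracle(shell, model, StimulusSet(np.array([src])))
    assert (do.times >= am.times - 1e-9).all()


def test_oracle_gap_on_random_meshes_and_tensors():
    """Empirical eikonal/oracle agreement sweep: random jittered-Delaunay
    meshes with random SPD tensors, 5 seeds; max relative gap < 8% beyond the
    near-source region (3 mean edge lengths, where both discretizations carry
    their O(h) source singularity error)."""
    worst = 0.0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        mesh = jittered_delaunay_mesh(rng)
        T = random_spd_tensors(rng, mesh.n_tets)
        model = ConductionModel(
            tensors=T, region=np.zeros(mesh.n_tets, dtype=np.int64),
            params=ConductionParams(1.0),
        )
        src = np.array([int(rng.integers(mesh.n_nodes))])
        am = solve_eikonal(mesh, model, StimulusSet(src))
        do = dijkstra_oracle(mesh, model, StimulusSet(src))
        d = np.linalg.norm(mesh.nodes - mesh.nodes[src[0]], axis=1)
        far = np.isfinite(am.times) & (d > 3.0 * mesh.mean_edge_length())
        gap = np.abs(do.times[far] - am.times[far]) / am.times[far]
        worst = max(worst, float(gap.max()))
    assert worst < 0.08


def test_speed_homogeneity_exact(iso_slab):
    mesh, model, src = iso_slab
    stim = StimulusSet(np.array([src]))
    t1 = solve_eikonal(mesh, model, stim).times
    k = 2.5
    fast = ConductionModel(
        tensors=model.tensors * k**2, region=model.region,
        params=ConductionParams(cv_long=k),
    )
    tk = solve_eikonal(mesh, fast, stim).times
    # agreement limited only by the 1e-6 ms convergence tolerance
    assert np.abs(tk * k - t1).max() < 1e-5


def test_geometric_scaling_exact(iso_slab):
    mesh, model, src = iso_slab
    stim = StimulusSet(np.array([src]))
    t1 = solve_eikonal(mesh, model, stim).times
    s = 1.7
    scaled = TetMesh(
        nodes=mesh.nodes * s, tets=mesh.tets,
        boundary_faces=mesh.boundary_faces, boundary_labels=mesh.boundary_labels,
    )
    ts = solve_eikonal(scaled, model, stim).times
    assert np.abs(ts - s * t1).max() < 1e-5


def test_causality_along_edges(iso_slab):
    mesh, model, src = iso_slab
    t = solve_eikonal(mesh, model, StimulusSet(np.array([src]))).times
    e = mesh.edges()
    elen = np.linalg.norm(mesh.nodes[e[:, 0]] - mesh.nodes[e[:, 1]], axis=1)
    # unit speed: |t(u) - t(v)| cannot exceed the edge metric length
    assert (np.abs(t[e[:, 0]] - t[e[:, 1]]) <= elen + 1e-6).all()


def test_total_activation_time_saturated_and_homogeneity(iso_slab):
    mesh, model, src = iso_slab
    all_nodes = StimulusSet(np.arange(mesh.n_nodes))
    assert total_activation_time(solve_eikonal(mesh, model, all_nodes)) == 0.0
    stim = StimulusSet(np.array([src]))
    tat = total_activation_time(solve_eikonal(mesh, model, stim))
    corner = np.linalg.norm([20.0, 10.0, 10.0])
    assert tat == pytest.approx(corner, rel=0.02)
    double = ConductionModel(
        tensors=4.0 * model.tensors, region=model.region, params=ConductionParams(2.0)
    )
    tat2 = total_activation_time(solve_eikonal(mesh, double, stim))
    assert tat2 == pytest.approx(tat / 2.0, rel=1e-12)


def test_unreachable_nodes_flagged_and_rejected():
    a = make_box((4.0, 4.0, 4.0), 2.0)
    b = make_box((4.0, 4.0, 4.0), 2.0, origin=(100.0, 0.0, 0.0))
    nodes = np.vstack([a.nodes, b.nodes])
    tets = np.vstack([a.tets, b.tets + a.n_nodes])
    mesh = TetMesh.create(nodes, tets, validate=False)
    model = ConductionModel(
        tensors=np.tile(np.eye(3), (mesh.n_tets, 1, 1)),
        region=np.zeros(mesh.n_tets, dtype=np.int64),
        params=ConductionParams(1.0),
    )
    amap = solve_eikonal(mesh, model, StimulusSet(np.array([0])))
    assert len(amap.unreachable) == b.n_nodes
    with pytest.raises(UnreachableNodesError):
        total_activation_time(amap)


def test_non_spd_tensor_rejected(iso_slab):
    mesh, model, src = iso_slab
    bad = model.tensors.copy()
    bad[0] = -np.eye(3)
    broken = ConductionModel(tensors=bad, region=model.region, params=model.params)
    with pytest.raises(ValueError):
        solve_eikonal(mesh, broken, StimulusSet(np.array([src])))


def test_deterministic_across_runs(iso_slab):
    mesh, model, src = iso_slab
    stim = StimulusSet(np.array([src]))
    t1 = solve_eikonal(mesh, model, stim).times
    t2 = solve_eikonal(mesh, model, stim).times
    assert (t1 == t2).all()
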