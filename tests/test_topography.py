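"""Topography statistic, ROIs, gradient fields, rotations, geodesics."""

import numpy as np
import pytest

from emomap.synthetic import gen_mesh
from emomap.topography import (
    DistanceMatrix,
    Mesh,
    VoxelGrid,
    anatomical_distance,
    functional_distance,
    geodesic_distance,
    gradient_direction,
    grid_for_sphere,
    per_dimension_topography,
    radius_sweep,
    rotation_analysis,
    sphere_roi,
    topography_stat,
)


# ---------------------------------------------------------------------------
# ROIs


def test_tiny_radius_keeps_only_center_voxel():
    grid = grid_for_sphere(np.zeros(3), 9.0, 3.0)
    roi = sphere_roi(np.zeros(3), 1.0, grid)
    assert roi.n_voxels == 1
    assert np.allclose(roi.coords[0], 0.0)


def test_radius_equal_to_spacing_gives_face_neighbors():
    grid = grid_for_sphere(np.zeros(3), 9.0, 3.0)
    roi = sphere_roi(np.zeros(3), 3.0, grid)
    # exhaustive oracle: center + 6 face neighbors at exactly 3 mm
    assert roi.n_voxels == 7
    d = np.linalg.norm(roi.coords, axis=1)
    assert np.isclose(sorted(d)[0], 0.0) and np.allclose(sorted(d)[1:], 3.0)


def test_sphere_roi_rejects_outside_center_and_empty():
    grid = VoxelGrid(shape=(5, 5, 5), voxel_size=3.0)
    with pytest.raises(ValueError, match="outside"):
        sphere_roi(np.array([100.0, 0, 0]), 3.0, grid)


def test_paper_scale_radius_sweep_range_supported(planted_roi):
    # 9-27 mm radii all produce valid ROIs on a covering grid
    grid = grid_for_sphere(np.zeros(3), 27.0, 3.0)
    sizes = [sphere_roi(np.zeros(3), r, grid).n_voxels for r in range(9, 28, 3)]
    assert sizes == sorted(sizes) and sizes[0] >= 100


# ---------------------------------------------------------------------------
# distance matrices


def test_functional_distance_pythagorean():
    d = functional_distance(np.array([[0.0, 0.0], [3.0, 4.0]]))
    assert np.isclose(d.values[0, 1], 5.0)
    assert d.values[0, 0] == 0


def test_functional_distance_matches_brute_force(rng):
    beta = rng.standard_normal((20, 4))
    d = functional_distance(beta).values
    for i in range(20):
        for j in range(20):
            assert np.isclose(d[i, j], np.linalg.norm(beta[i] - beta[j]))


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), "euclidean")
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), "euclidean")


# ---------------------------------------------------------------------------
# topography statistic


def test_monotone_transform_of_anatomy_gives_rho_one(planted_roi):
    roi = planted_roi["roi"]
    anat = anatomical_distance(roi)
    func = DistanceMatrix(np.sqrt(anat.values) * 3.7, metric="beta_euclidean")
    stat = topography_stat(anat, func, n_boot=0)
    assert np.isclose(stat.rho, 1.0)


def test_constant_beta_is_degenerate_not_zero(planted_roi):
    roi = planted_roi["roi"]
    anat = anatomical_distance(roi)
    stat = per_dimension_topography(anat, np.full(roi.n_voxels, 2.5), n_boot=0)
    assert stat.degenerate and np.isnan(stat.rho)


def test_rho_invariant_under_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    from emomap.topography import VoxelROI

    # generic (tie-free) voxel positions inside a ball: lattice coordinates
    # have exactly tied distances whose ranks are unstable under a
    # floating-point rotation, which would obscure the invariance
    pts = rng.standard_normal((80, 3))
    pts = 12.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True) * rng.uniform(
        0.2, 1.0, (80, 1)
    )
    roi = VoxelROI(coords=pts, center=np.zeros(3), radius=12.0, voxel_ids=np.arange(80))
    beta = pts @ np.array([1.0, -0.5, 0.25]) + 0.1 * rng.standard_normal(80)
    rot = Rotation.random(random_state=np.random.default_rng(3)).as_matrix()
    shift = np.array([10.0, -4.0, 2.0])
    moved = VoxelROI(
        coords=pts @ rot.T + shift,
        center=shift,
        radius=12.0,
        voxel_ids=np.arange(80),
    )
    f = functional_distance(beta)
    s0 = topography_stat(anatomical_distance(roi), f, n_boot=0)
    s1 = topography_stat(anatomical_distance(moved), f, n_boot=0)
    assert np.isclose(s0.rho, s1.rho, atol=1e-9)


def test_bootstrap_ci_brackets_point_estimate(planted_roi):
    roi = planted_roi["roi"]
    anat = anatomical_distance(roi)
    func = functional_distance(planted_roi["beta"])
    stat = topography_stat(anat, func, n_boot=100, seed=1)
    lo, hi = stat.ci
    assert lo <= stat.rho <= hi


def test_mismatched_sizes_and_too_small_roi_rejected():
    a = DistanceMatrix(np.zeros((3, 3)), "euclidean")
    b = DistanceMatrix(np.zeros((4, 4)), "beta_euclidean")
    with pytest.raises(ValueError, match="differ in size"):
        topography_stat(a, b)
    with pytest.raises(ValueError, match="4 voxels"):
        topography_stat(a, a)


# ---------------------------------------------------------------------------
# radius sweep


def test_radius_sweep_tie_breaks_toward_smaller_radius():
    grid = grid_for_sphere(np.zeros(3), 12.0, 3.0)
    coords = grid.coords()

    def beta_provider(roi):
        return roi.coords[:, :1]  # perfect x gradient at every radius

    def null_provider(roi):
        rng = np.random.default_rng(0)
        return rng.standard_normal((30, roi.n_voxels, 1))

    res = radius_sweep(
        np.zeros(3), [6.0, 9.0, 12.0], grid, beta_provider, null_provider
    )
    assert res.selected_radius is not None
    sig = {
        r: s for r, s in res.stats.items() if s.p is not None and s.p < 0.05
    }
    best_rho = max(s.rho for s in sig.values())
    expected = min(r for r, s in sig.items() if np.isclose(s.rho, best_rho))
    assert res.selected_radius == expected


def test_radius_sweep_with_no_signal_selects_nothing(rng):
    grid = grid_for_sphere(np.zeros(3), 12.0, 3.0)

    def beta_provider(roi):
        return np.random.default_rng(1).standard_normal((roi.n_voxels, 1))

    def null_provider(roi):
        return np.random.default_rng(2).standard_normal((200, roi.n_voxels, 1))

    res = radius_sweep(
        np.zeros(3), [6.0, 9.0], grid, beta_provider, null_provider, alpha=0.001
    )
    assert res.selected_radius is None
    assert set(res.stats) == {6.0, 9.0}


# ---------------------------------------------------------------------------
# gradient direction


def test_beta_equal_x_gives_x_direction(planted_roi):
    roi = planted_roi["roi"]
    gf = gradient_direction(roi, roi.coords[:, 0])
    assert np.allclose(gf.principal_direction, [1, 0, 0], atol=1e-9)
    interior = np.isfinite(gf.vectors).all(axis=1)
    assert np.allclose(gf.vectors[interior], [1, 0, 0], atol=1e-9)


def test_beta_x_plus_y_gives_diagonal(planted_roi):
    roi = planted_roi["roi"]
    gf = gradient_direction(roi, roi.coords[:, 0] + roi.coords[:, 1])
    assert np.allclose(
        gf.principal_direction, [1 / np.sqrt(2), 1 / np.sqrt(2), 0], atol=1e-6
    )


def test_constant_beta_yields_null_direction(planted_roi):
    roi = planted_roi["roi"]
    gf = gradient_direction(roi, np.zeros(roi.n_voxels))
    assert gf.null_flag and gf.principal_direction is None
    assert gf.magnitude == 0.0


def test_single_voxel_roi_rejected():
    grid = grid_for_sphere(np.zeros(3), 9.0, 3.0)
    roi = sphere_roi(np.zeros(3), 1.0, grid)
    with pytest.raises(ValueError, match="single voxel"):
        gradient_direction(roi, np.array([1.0]))


# ---------------------------------------------------------------------------
# rotation analysis


def test_rotation_analysis_contracts(planted_roi):
    roi = planted_roi["roi"]
    beta = planted_roi["beta"]
    anat = anatomical_distance(roi)
    with pytest.raises(ValueError, match="10 rotations"):
        rotation_analysis(beta, anat, n_rotations=5)
    with pytest.raises(ValueError, match="N, 3"):
        rotation_analysis(beta[:, :2], anat)
    ra = rotation_analysis(beta, anat, n_rotations=12, seed=0)
    assert ra.rhos.shape == (12, 3)
    # identity per-dimension rhos agree with the direct statistic
    for d in range(3):
        direct = per_dimension_topography(anat, beta[:, d], n_boot=0).rho
        assert np.isclose(ra.identity_rhos[d], direct, atol=1e-9)
    assert 1 <= ra.identity_rank <= 13


def test_rotation_analysis_is_seed_deterministic(planted_roi):
    roi = planted_roi["roi"]
    anat = anatomical_distance(roi)
    a = rotation_analysis(planted_roi["beta"], anat, n_rotations=15, seed=5)
    b = rotation_analysis(planted_roi["beta"], anat, n_rotations=15, seed=5)
    assert np.array_equal(a.rhos, b.rhos)


# ---------------------------------------------------------------------------
# meshes and geodesics


def test_plane_resolution_two_is_two_triangles():
    mesh = gen_mesh("plane", 2, size=10.0)
    assert mesh.n_vertices == 4
    assert len(mesh.triangles) == 2


def test_sphere_vertices_on_radius():
    mesh = gen_mesh("sphere", 2, size=7.0)
    assert np.allclose(np.linalg.norm(mesh.vertices, axis=1), 7.0, atol=1e-9)


def test_unknown_mesh_kind_rejected():
    with pytest.raises(ValueError, match="unknown mesh kind"):
        gen_mesh("torus", 3)


def test_adjacent_vertices_distance_equals_edge_length():
    mesh = gen_mesh("plane", 3, size=10.0)
    e = mesh.edges()
    d = geodesic_distance(mesh).values
    for i, j in e:
        assert np.isclose(
            d[i, j], np.linalg.norm(mesh.vertices[i] - mesh.vertices[j])
        )


def test_geodesic_matches_brute_force_bellman_ford():
    import networkx as nx

    mesh = gen_mesh("sphere", 2, size=5.0)  # small icosphere
    sub = np.arange(min(30, mesh.n_vertices))
    d = geodesic_distance(mesh, sub).values
    g = nx.Graph()
    for i, j in mesh.edges():
        g.add_edge(
            int(i), int(j), weight=float(np.linalg.norm(mesh.vertices[i] - mesh.vertices[j]))
        )
    oracle = dict(nx.all_pairs_bellman_ford_path_length(g, weight="weight"))
    for a in range(len(sub)):
        for b in range(len(sub)):
            assert np.isclose(d[a, b], oracle[int(sub[a])][int(sub[b])], atol=1e-9)


def test_plane_graph_distance_bounded_below_by_euclidean():
    mesh = gen_mesh("plane", 10, size=30.0)
    ids = np.array([0, mesh.n_vertices - 1])  # opposite corners
    d = geodesic_distance(mesh, ids).values[0, 1]
    assert d >= np.linalg.norm(mesh.vertices[ids[0]] - mesh.vertices[ids[1]]) - 1e-9


def test_disconnected_mesh_flags_infinite_distances():
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 0], [6, 5, 0], [5, 6, 0]],
        dtype=float,
    )
    t = np.array([[0, 1, 2], [3, 4, 5]])
    with pytest.warns(UserWarning, match="components"):
        d = geodesic_distance(Mesh(v, t))
    assert d.disconnected and np.isinf(d.values[0, 3])


def test_mesh_validation_rejects_bad_input():
    with pytest.raises(ValueError, match="out of range"):
        Mesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))
    v = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
    with pytest.raises(ValueError, match="zero-length"):
        Mesh(v, np.array([[0, 1, 2]]))
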