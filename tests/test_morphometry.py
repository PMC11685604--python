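"""Filament/tree morphometrics and voxel-surface geodesics."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_tree
from deepstain3d.grid import DistanceField, MaskVolume
from deepstain3d.morphometry import (
    SurfaceGraph,
    TracedPath,
    TracedTree,
    classify_reacher,
    geodesic_distance,
    horton_strahler,
    minimal_distance,
    nn_geodesic_stats,
    path_displacement,
    path_length,
    read_swc_path,
    read_swc_tree,
    sholl_analysis,
    takeoff_angle,
    tortuosity_skewness,
    write_swc,
)


def planar_field(n=30, spacing=(1.0, 1.0, 1.0)):
    """Distance field measuring distance from the x = 0 plane."""
    x = np.arange(n) * spacing[2]
    return DistanceField(np.broadcast_to(x, (n, n, n)).copy(), spacing)


class TestScalarMetrics:
    def test_three_four_five(self):
        p = TracedPath(np.array([[0.0, 0, 0], [0, 3, 4]]))
        assert path_length(p) == pytest.approx(5.0)
        assert path_displacement(p) == pytest.approx(5.0)

    def test_loop_has_zero_displacement(self):
        p = TracedPath(np.array([[0.0, 0, 0], [0, 1, 0], [0, 1, 1], [0, 0, 0]]))
        assert path_length(p) > 0
        assert path_displacement(p) == 0.0

    def test_single_point_raises(self):
        p = TracedPath(np.array([[0.0, 0, 0]]))
        with pytest.raises(ValueError):
            path_length(p)
        with pytest.raises(ValueError):
            path_displacement(p)

    def test_helix_arc_length_closed_form(self):
        a, omega, H = 3.0, 4 * np.pi, 20.0
        t = np.linspace(0, 1, 50001)
        pts = np.stack([H * t, a * np.cos(omega * t), a * np.sin(omega * t)], axis=1)
        p = TracedPath(pts)
        assert path_length(p) == pytest.approx(math.sqrt(H**2 + a**2 * omega**2), rel=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(*[st.floats(-50, 50)] * 3), min_size=2, max_size=12, unique=True))
    def test_displacement_never_exceeds_length(self, pts):
        p = TracedPath(np.array(pts, dtype=float))
        assert path_displacement(p) <= path_length(p) + 1e-9

    def test_minimal_distance_planar(self):
        field = planar_field()
        p = TracedPath(np.array([[5.0, 5.0, 0.0], [5.0, 5.0, 20.0]]))
        assert minimal_distance(p, field) == pytest.approx(20.0)
        same = TracedPath(np.array([[5.0, 5.0, 10.0], [5.0, 20.0, 10.0]]))
        assert minimal_distance(same, field) == 0.0

    def test_minimal_distance_outside_domain_raises(self):
        with pytest.raises(ValueError, match="outside"):
            minimal_distance(TracedPath(np.array([[0.0, 0, 0], [0, 0, 500.0]])), planar_field())

    def test_tortuosity_and_skewness(self):
        tort, skew = tortuosity_skewness(10.0, 5.0, 2.0)
        assert tort == 2.0 and skew == 2.5
        tort, skew = tortuosity_skewness(10.0, 0.0, 0.0)
        assert math.isnan(tort) and math.isnan(skew)

    def test_semicircle_tortuosity(self):
        r = 10.0
        theta = np.linspace(0, np.pi, 2001)
        pts = np.stack([np.zeros_like(theta) + 15, 15 + r * np.sin(theta), 15 + r * np.cos(theta)], axis=1)
        p = TracedPath(pts)
        d_p, d_f = path_length(p), path_displacement(p)
        assert d_p / d_f == pytest.approx(np.pi / 2, rel=1e-5)


class TestTakeoffAngle:
    @pytest.mark.parametrize(
        "end,expected",
        [((5.0, 15.0, 25.0), 0.0), ((5.0, 25.0, 15.0), 90.0), ((5.0, 15.0, 5.0), 180.0)],
    )
    def test_cardinal_angles_against_planar_gradient(self, end, expected):
        field = planar_field()  # gradient points along +x
        p = TracedPath(np.array([[5.0, 15.0, 15.0], list(end)]))
        assert takeoff_angle(p, field) == pytest.approx(expected, abs=1e-6)

    def test_zero_gradient_is_nan(self):
        flat = DistanceField(np.zeros((10, 10, 10)))
        p = TracedPath(np.array([[5.0, 5, 5], [5, 5, 8]]))
        assert math.isnan(takeoff_angle(p, flat))


class TestReacherClassification:
    def test_end_on_mask_is_reacher(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[:, :, 8] = True
        pec = MaskVolume(mask)
        reach = TracedPath(np.array([[5.0, 5, 0], [5, 5, 8]]))
        stay = TracedPath(np.array([[5.0, 5, 0], [5, 5, 4]]))
        assert classify_reacher(reach, pec, tolerance=0.5)
        assert not classify_reacher(stay, pec, tolerance=0.5)

    def test_phantom_classification_matches_truth(self, glom_phantom):
        ph = glom_phantom
        for p, (_, row) in zip(ph.paths, ph.truth_metrics.iterrows()):
            assert classify_reacher(p, ph.pec_mask, tolerance=2.0) == row.is_reacher


def _random_surface_patch(seed, size=12):
    """Surface of a random blob mask; small enough for exhaustive oracles."""
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(*[np.arange(size)] * 3, indexing="ij")
    c = rng.uniform(3, size - 3, 3)
    r = rng.uniform(2.5, 4.5)
    mask = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
    spacing = tuple(rng.uniform(0.5, 2.0, 3))
    return MaskVolume(mask, spacing)


def _nx_graph(surface: SurfaceGraph) -> nx.Graph:
    """Independent reconstruction of the surface graph for oracle checks."""
    g = nx.Graph()
    coords = [tuple(c) for c in surface.coords]
    g.add_nodes_from(range(len(coords)))
    spc = np.asarray(surface.spacing)
    index = {c: i for i, c in enumerate(coords)}
    for i, c in enumerate(coords):
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    nb = (c[0] + dz, c[1] + dy, c[2] + dx)
                    j = index.get(nb)
                    if j is not None:
                        w = float(np.linalg.norm(np.array([dz, dy, dx]) * spc))
                        g.add_edge(i, j, weight=w)
    return g


class TestGeodesics:
    def test_identity_and_face_adjacency(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1:3, 1] = True
        surf = SurfaceGraph.from_mask(MaskVolume(mask))
        p, q = (1, 1, 1), (1, 2, 1)
        assert geodesic_distance(surf, p, p) == 0.0
        assert geodesic_distance(surf, p, q) == pytest.approx(1.0)

    def test_off_surface_voxel_raises(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        surf = SurfaceGraph.from_mask(MaskVolume(mask))
        with pytest.raises(ValueError, match="surface"):
            surf.node_of((2, 2, 2))  # interior voxel

    def test_matches_bellman_ford_oracle(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            mask = _random_surface_patch(seed)
            surf = SurfaceGraph.from_mask(mask)
            g = _nx_graph(surf)
            n = len(surf)
            pairs = rng.integers(0, n, size=(20, 2))
            for i, j in pairs:
                expected = nx.bellman_ford_path_length(g, int(i), int(j), weight="weight")
                got = surf.distances_from([int(i)])[0, int(j)]
                assert got == pytest.approx(expected, abs=1e-9)

    def test_metric_properties_and_euclidean_lower_bound(self):
        mask = _random_surface_patch(3)
        surf = SurfaceGraph.from_mask(mask)
        rng = np.random.default_rng(4)
        n = len(surf)
        d = surf.distances_from(list(range(n)))
        spc = np.asarray(surf.spacing)
        for _ in range(30):
            i, j, k = rng.integers(0, n, 3)
            assert d[i, j] == pytest.approx(d[j, i], abs=1e-9)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9
            eucl = np.linalg.norm((surf.coords[i] - surf.coords[j]) * spc)
            assert d[i, j] >= eucl - 1e-9


class TestNNGeodesicStats:
    def _plane_surface(self, n=30):
        mask = np.zeros((1, 3, n), dtype=bool)
        mask[0, 1, :] = True
        return SurfaceGraph.from_mask(MaskVolume(mask))

    def test_two_points_symmetric(self):
        surf = self._plane_surface()
        pts = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 9.0]])
        out = nn_geodesic_stats(pts, surf)
        assert out["nn_geodesic"].iloc[0] == out["nn_geodesic"].iloc[1] == pytest.approx(7.0)

    def test_three_collinear_points(self):
        surf = self._plane_surface()
        pts = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 10.0], [0.0, 1.0, 25.0]])
        out = nn_geodesic_stats(pts, surf)
        np.testing.assert_allclose(out["nn_geodesic"], [10.0, 10.0, 15.0])

    def test_clustered_points_separate(self):
        surf = self._plane_surface(60)
        near = [[0.0, 1.0, float(x)] for x in (0, 2, 4)]
        far = [[0.0, 1.0, float(x)] for x in (50, 52, 54)]
        out = nn_geodesic_stats(np.array(near + far), surf)
        assert out["nn_geodesic"].max() <= 2.0  # within-cluster NN only

    def test_correlation_attrs(self, glom_phantom):
        surf = SurfaceGraph.from_mask(glom_phantom.glom_mask)
        lengths = [path_length(p) for p in glom_phantom.paths]
        out = nn_geodesic_stats(glom_phantom.attachment_points, surf, path_lengths=lengths)
        assert "pearson_r" in out.attrs and "spearman_r" in out.attrs
        assert -1 <= out.attrs["pearson_r"] <= 1

    def test_single_point_raises(self):
        surf = self._plane_surface()
        with pytest.raises(ValueError):
            nn_geodesic_stats(np.array([[0.0, 1.0, 2.0]]), surf)


def sholl_oracle(tree: TracedTree, center, radii, step=0.01):
    """Dense-resampling crossing counter (independent oracle)."""
    center = np.asarray(center, dtype=float)
    counts = np.zeros(len(radii), dtype=int)
    for p0, p1 in tree.edges():
        seg_len = np.linalg.norm(p1 - p0)
        n = max(int(np.ceil(seg_len / step)), 2)
        t = np.linspace(0, 1, n + 1)
        pts = p0[None] + t[:, None] * (p1 - p0)[None]
        r = np.linalg.norm(pts - center, axis=1)
        for k, radius in enumerate(radii):
            s = np.sign(r - radius)
            counts[k] += int(np.sum(s[:-1] * s[1:] < 0))
    return counts


class TestSholl:
    def test_single_straight_branch(self):
        nodes = {1: np.zeros(3), 2: np.array([0.0, 0.0, 10.0])}
        tree = TracedTree(nodes, {1: None, 2: 1})
        counts = sholl_analysis(tree, (0, 0, 0), [2.0, 5.0, 9.0, 12.0])
        np.testing.assert_array_equal(counts, [1, 1, 1, 0])

    def test_y_tree_bifurcation(self):
        nodes = {
            1: np.zeros(3),
            2: np.array([0.0, 0.0, 5.0]),
            3: np.array([0.0, 3.0, 9.0]),
            4: np.array([0.0, -3.0, 9.0]),
        }
        tree = TracedTree(nodes, {1: None, 2: 1, 3: 2, 4: 2})
        counts = sholl_analysis(tree, (0, 0, 0), [3.0, 7.0])
        np.testing.assert_array_equal(counts, [1, 2])

    def test_matches_dense_resampling_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            tree = random_tree(rng, n_nodes=20)
            center = rng.uniform(5, 15, 3)
            radii = np.sort(rng.uniform(1, 20, 5))
            got = sholl_analysis(tree, center, radii)
            np.testing.assert_array_equal(got, sholl_oracle(tree, center, radii))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(9)
        tree = random_tree(rng, n_nodes=15)
        center = np.array([10.0, 10.0, 10.0])
        radii = [2.0, 5.0, 8.0, 12.0]
        base = sholl_analysis(tree, center, radii)
        # rotate 90° about z: (z, y, x) -> (z, x, -y)
        rot_nodes = {
            k: np.array([v[0], v[2], -v[1]]) for k, v in tree.nodes.items()
        }
        rot_tree = TracedTree(rot_nodes, dict(tree.parents))
        rot_center = np.array([center[0], center[2], -center[1]])
        np.testing.assert_array_equal(sholl_analysis(rot_tree, rot_center, radii), base)

    def test_empty_radii_raises(self):
        tree = TracedTree({1: np.zeros(3), 2: np.ones(3)}, {1: None, 2: 1})
        with pytest.raises(ValueError):
            sholl_analysis(tree, (0, 0, 0), [])


def strahler_oracle(tree: TracedTree, node=None) -> int:
    """Direct recursive Strahler definition (independent oracle)."""
    children = tree.children()

    def order(n):
        ch = children[n]
        if not ch:
            return 1
        sub = sorted(order(c) for c in ch)
        m = sub[-1]
        return m + 1 if len(sub) >= 2 and sub[-2] == m else m

    return order(tree.root if node is None else node)


class TestStrahler:
    def test_unbranched_path(self):
        nodes = {i: np.array([0.0, 0.0, float(i)]) for i in range(1, 6)}
        parents = {1: None, **{i: i - 1 for i in range(2, 6)}}
        assert horton_strahler(TracedTree(nodes, parents)) == 1

    def test_perfect_binary_tree_depth3(self):
        nodes, parents = {1: np.zeros(3)}, {1: None}
        nid = 2
        frontier = [1]
        for _depth in range(3):
            nxt = []
            for p in frontier:
                for _ in range(2):
                    nodes[nid] = np.random.default_rng(nid).uniform(0, 1, 3)
                    parents[nid] = p
                    nxt.append(nid)
                    nid += 1
            frontier = nxt
        assert horton_strahler(TracedTree(nodes, parents)) == 4  # depth 3 + root level

    def test_matches_recursive_oracle_on_random_trees(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            tree = random_tree(rng, n_nodes=50)
            assert horton_strahler(tree) == strahler_oracle(tree)

    def test_child_order_permutation_invariance(self):
        rng = np.random.default_rng(11)
        tree = random_tree(rng, n_nodes=30)
        base = horton_strahler(tree)
        relabel = {old: new for new, old in enumerate(rng.permutation(list(tree.nodes)), 1)}
        nodes = {relabel[k]: v for k, v in tree.nodes.items()}
        parents = {relabel[k]: (None if p is None else relabel[p]) for k, p in tree.parents.items()}
        assert horton_strahler(TracedTree(nodes, parents)) == base

    def test_malformed_tree_raises(self):
        with pytest.raises(ValueError):
            TracedTree({1: np.zeros(3), 2: np.ones(3)}, {1: 2, 2: 1})  # cycle, no root


class TestSWC:
    def test_path_roundtrip(self, tmp_path):
        p = TracedPath(np.array([[0.0, 1.0, 2.0], [3.0, 4.0, 5.0], [6.0, 7.0, 8.0]]), id="f1")
        f = tmp_path / "path.swc"
        write_swc(f, p)
        back = read_swc_path(f)
        np.testing.assert_allclose(back.points, p.points)

    def test_tree_roundtrip_preserves_strahler(self, tmp_path):
        rng = np.random.default_rng(12)
        tree = random_tree(rng, n_nodes=25)
        f = tmp_path / "tree.swc"
        write_swc(f, tree)
        back = read_swc_tree(f)
        assert horton_strahler(back) == horton_strahler(tree)
        np.testing.assert_allclose(back.nodes[tree.root], tree.nodes[tree.root])

    def test_branching_trace_rejected_as_path(self, tmp_path):
        nodes = {1: np.zeros(3), 2: np.ones(3), 3: np.array([0.0, 0, 2]), 4: np.array([0.0, 2, 0])}
        tree = TracedTree(nodes, {1: None, 2: 1, 3: 2, 4: 2})
        f = tmp_path / "branch.swc"
        write_swc(f, tree)
        with pytest.raises(ValueError, match="branches"):
            read_swc_path(f)
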