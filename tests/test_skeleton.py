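"""Skeleton graph construction, neck finding, and exact longest-path search."""

import math

import networkx as nx
import numpy as np
import pytest

from paniclekit.errors import DomainError
from paniclekit.skeleton import (
    SQRT2,
    find_neck,
    longest_path_from,
    path_polyline_length,
    prune_stalk,
    skeletonize_mask,
)


def graph_from_edges(edges):
    g = nx.Graph()
    for u, v in edges:
        w = 1.0 if (u[0] == v[0] or u[1] == v[1]) else SQRT2
        g.add_edge(u, v, weight=w)
    return g


def chain(points):
    return list(zip(points[:-1], points[1:]))


def brute_force_longest(g, start):
    best = 0.0
    for target in g.nodes:
        if target == start:
            continue
        for path in nx.all_simple_paths(g, start, target):
            w = sum(g[a][b]["weight"] for a, b in zip(path[:-1], path[1:]))
            best = max(best, w)
    return best


def random_skeleton_graph(rng, n_max=25):
    """Random connected graph on grid-like nodes with {1, sqrt2} weights."""
    n = int(rng.integers(5, n_max + 1))
    g = nx.Graph()
    nodes = [(0, 0)]
    g.add_node((0, 0))
    while len(nodes) < n:
        base = nodes[rng.integers(len(nodes))]
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        if dr == 0 and dc == 0:
            continue
        nb = (base[0] + int(dr), base[1] + int(dc))
        w = 1.0 if dr * dc == 0 else SQRT2
        if nb not in g:
            nodes.append(nb)
        g.add_edge(base, nb, weight=w)
    # sprinkle extra edges to create cycles
    for _ in range(int(rng.integers(0, 4))):
        a = nodes[rng.integers(len(nodes))]
        b = (a[0] + int(rng.integers(-1, 2)), a[1] + int(rng.integers(-1, 2)))
        if b in g and a != b:
            w = 1.0 if a[0] == b[0] or a[1] == b[1] else SQRT2
            g.add_edge(a, b, weight=w)
    return g


class TestSkeletonize:
    def test_horizontal_bar_is_single_path(self):
        mask = np.zeros((20, 110), bool)
        mask[8:13, 5:105] = True
        g = skeletonize_mask(mask)
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        assert len(endpoints) == 2
        assert nx.is_connected(g)
        assert all(g.degree(n) <= 2 for n in g.nodes)

    def test_filled_disk_collapses(self):
        from skimage import draw

        mask = np.zeros((60, 60), bool)
        rr, cc = draw.disk((30, 30), 20)
        mask[rr, cc] = True
        g = skeletonize_mask(mask)
        if g.number_of_nodes() > 1:
            start = next(iter(g.nodes))
            _, length = longest_path_from(g, start)
            assert length <= 20

    def test_y_mask_topology(self):
        mask = np.zeros((60, 60), bool)
        mask[30:55, 30] = True  # stalk down
        for i in range(25):  # two arms up
            mask[30 - i, 30 - i] = True
            mask[30 - i, 30 + i] = True
        g = skeletonize_mask(mask)
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        branch = [n for n in g.nodes if g.degree(n) >= 3]
        assert len(endpoints) == 3
        assert len(branch) == 1

    def test_empty_mask_raises(self):
        with pytest.raises(DomainError):
            skeletonize_mask(np.zeros((10, 10), bool))


class TestFindNeck:
    def test_single_junction(self):
        g = graph_from_edges(
            chain([(100, 50), (90, 50), (80, 50)])  # stalk below junction
            + chain([(80, 50), (70, 45), (60, 40)])
            + chain([(80, 50), (70, 55), (60, 60)])
        )
        assert find_neck(g) == (80, 50)

    def test_straight_line_falls_back_to_bottom_endpoint(self):
        g = graph_from_edges(chain([(10, 5), (20, 5), (30, 5), (40, 5)]))
        assert find_neck(g) == (40, 5)

    def test_lowest_of_two_branch_points(self):
        # junctions at rows 60 and 90; below row 90 only a bare stalk
        g = graph_from_edges(
            chain([(120, 50), (110, 50), (100, 50), (90, 50)])
            + chain([(90, 50), (80, 45), (70, 40), (60, 40)])
            + chain([(90, 50), (80, 55), (70, 55), (60, 55)])
            + chain([(60, 40), (50, 35)])
            + chain([(60, 40), (50, 45)])
        )
        assert find_neck(g) == (90, 50)

    def test_low_lobe_junction_skipped(self):
        # the lowest junction (110, 60) sits on a grain lobe: the rest of
        # the skeleton — including other junctions — hangs "below" it, so
        # it is rejected in favour of the lowest axis junction (100, 50),
        # whose downward branch is a clean bare stalk
        g = graph_from_edges(
            chain([(130, 50), (120, 50), (110, 50)])  # stalk
            + chain([(110, 50), (100, 50), (90, 50), (80, 50), (70, 50), (60, 50)])  # axis
            + chain([(100, 50), (105, 56), (110, 60)])  # drooping lobe
            + chain([(110, 60), (115, 63)])
            + chain([(110, 60), (110, 66)])
            + chain([(80, 50), (75, 45)])
            + chain([(80, 50), (75, 55)])
        )
        assert find_neck(g) == (100, 50)


class TestPruneStalk:
    def test_y_stalk_removed(self):
        stalk = chain([(100, 50), (90, 50), (80, 50)])
        arm1 = chain([(80, 50), (70, 45), (60, 40)])
        arm2 = chain([(80, 50), (70, 55), (60, 60)])
        g = graph_from_edges(stalk + arm1 + arm2)
        out = prune_stalk(g, (80, 50))
        assert (100, 50) not in out and (90, 50) not in out
        assert (60, 40) in out and (60, 60) in out and (80, 50) in out

    def test_straight_line_unchanged(self):
        g = graph_from_edges(chain([(10, 5), (20, 5), (30, 5)]))
        out = prune_stalk(g, (30, 5))
        assert set(out.nodes) == set(g.nodes)


class TestLongestPath:
    def test_orthogonal_chain(self):
        nodes = [(0, i) for i in range(100)]
        g = graph_from_edges(chain(nodes))
        _, length = longest_path_from(g, (0, 0))
        assert length == pytest.approx(99.0)

    def test_y_takes_heavier_arm(self):
        neck = (50, 50)
        arm_a = [(50 - i, 50 - i) for i in range(1, 41)]
        arm_b = [(50 - i, 50 + i) for i in range(1, 26)]
        g = graph_from_edges(chain([neck] + arm_a) + chain([neck] + arm_b))
        path, length = longest_path_from(g, neck)
        assert length == pytest.approx(40 * SQRT2)
        assert path[-1] == arm_a[-1]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            g = random_skeleton_graph(rng)
            start = min(g.nodes)
            _, length = longest_path_from(g, start)
            assert length == pytest.approx(brute_force_longest(g, start), abs=1e-9)

    def test_tree_two_sweep_oracle(self):
        # on trees the longest simple path from a node is the weighted
        # eccentricity, computable independently by Dijkstra
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = random_skeleton_graph(rng)
            if g.number_of_edges() != g.number_of_nodes() - 1:
                continue
            start = min(g.nodes)
            _, length = longest_path_from(g, start)
            dist = nx.single_source_dijkstra_path_length(g, start)
            assert length == pytest.approx(max(dist.values()), abs=1e-9)

    def test_invariant_under_node_relabelling(self):
        rng = np.random.default_rng(5)
        g = random_skeleton_graph(rng)
        start = min(g.nodes)
        _, length = longest_path_from(g, start)
        shift = nx.relabel_nodes(g, {n: (n[0] + 7, n[1] + 3) for n in g.nodes})
        _, length2 = longest_path_from(shift, (start[0] + 7, start[1] + 3))
        assert length2 == pytest.approx(length, abs=1e-9)

    def test_geodesic_at_least_chord(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = random_skeleton_graph(rng)
            start = min(g.nodes)
            path, length = longest_path_from(g, start)
            chord = math.dist(path[0], path[-1])
            assert length >= chord - 1e-9

    def test_pruning_never_explores_more_states(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            g = random_skeleton_graph(rng)
            start = min(g.nodes)
            p1, l1, states_pruned = longest_path_from(g, start, count_states=True)
            p2, l2, states_full = longest_path_from(g, start, count_states=True, prune=False)
            assert l1 == pytest.approx(l2, abs=1e-9)
            assert states_pruned <= states_full


class TestPolylineLength:
    def test_straight_diagonal_chain_near_euclidean(self):
        path = [(i, i) for i in range(60)]
        assert path_polyline_length(path) == pytest.approx(59 * SQRT2, rel=0.01)

    def test_staircase_shorter_than_geodesic(self):
        # a 26.57-degree digital line: geodesic over-measures, the smoothed
        # polyline should land near the true Euclidean length
        path = []
        r = c = 0
        for _ in range(30):
            path += [(r, c), (r, c + 1)]
            r, c = r + 1, c + 2
        geodesic = sum(
            1.0 if a[0] == b[0] or a[1] == b[1] else SQRT2
            for a, b in zip(path[:-1], path[1:])
        )
        true_len = math.dist(path[0], path[-1])
        smooth = path_polyline_length(path)
        assert smooth < geodesic
        assert smooth == pytest.approx(true_len, rel=0.03)


class TestMeasurePanicleLength:
    def test_synthetic_panicle_within_five_percent(self, loose_scene):
        from paniclekit.skeleton import measure_panicle_length

        img, gt, cal, mask = loose_scene
        res = measure_panicle_length(img, cal, mask=mask)
        assert res.length_mm == pytest.approx(gt.axis_length_mm, rel=0.05)
        assert res.neck[0] > res.path[-1][0]  # neck below the tip
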