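"""MST extraction, pruning, rooting and ROI forests."""

import itertools

import numpy as np
import pytest

from vesseltrees.connectivity import GeodesicEdge, GeodesicGraph
from vesseltrees.scalespace import Volume
from vesseltrees.trees import (
    forest_by_roi,
    kruskal_mst,
    minimum_spanning_tree,
    prune,
    root_tree,
)


def _edge(a, b, F, L=None, pa=None, pb=None):
    pa = np.zeros(3) if pa is None else np.asarray(pa, float)
    pb = np.ones(3) if pb is None else np.asarray(pb, float)
    return GeodesicEdge(a=a, b=b, path=np.vstack([pa, pb]), F=F,
                        L=F if L is None else L)


def _random_graph(rng, n, m):
    g = GeodesicGraph(nodes=[rng.uniform(0, 10, 3) for _ in range(n)])
    pairs = list(itertools.combinations(range(n), 2))
    rng.shuffle(pairs)
    for a, b in pairs[:m]:
        g.add_edge(_edge(a, b, float(rng.uniform(0.1, 5.0)),
                         pa=g.nodes[a], pb=g.nodes[b]))
    return g


def _brute_force_mst_weight(g):
    """Exhaustive minimum over all spanning edge subsets."""
    n = len(g.nodes)
    edges = g.edge_list()
    best = None
    for sub in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for e in sub:
            ra, rb = find(e.a), find(e.b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            w = sum(e.F for e in sub)
            if best is None or w < best:
                best = w
    return best


class TestMST:
    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(8):
            n = int(rng.integers(4, 8))
            g = _random_graph(rng, n, min(n + 3, n * (n - 1) // 2))
            want = _brute_force_mst_weight(g)
            if want is None:  # disconnected draw
                continue
            got = sum(e.F for e in kruskal_mst(n, g.edge_list()))
            assert got == pytest.approx(want, rel=1e-12)

    def test_tree_input_returned_unchanged(self, rng):
        g = GeodesicGraph(nodes=[rng.uniform(0, 10, 3) for _ in range(5)])
        for a, b in [(0, 1), (1, 2), (1, 3), (3, 4)]:
            g.add_edge(_edge(a, b, 1.0, pa=g.nodes[a], pb=g.nodes[b]))
        t = minimum_spanning_tree(g)
        assert set(t.edges) == set(g.edges)

    def test_edge_count_invariant_per_component(self, rng):
        g = _random_graph(rng, 7, 12)
        t = minimum_spanning_tree(g)
        comps = t.components()
        assert t.n_edges == t.n_nodes - len(comps)

    def test_independent_of_edge_insertion_order(self, rng):
        g = _random_graph(rng, 6, 10)
        edges = g.edge_list()
        w1 = [(e.a, e.b) for e in kruskal_mst(6, edges)]
        w2 = [(e.a, e.b) for e in kruskal_mst(6, list(reversed(edges)))]
        assert sorted(w1) == sorted(w2)

    def test_empty_graph(self):
        t = minimum_spanning_tree(GeodesicGraph())
        assert t.n_nodes == 0 and t.n_edges == 0


def _chain_tree(positions, Fs=None):
    from vesseltrees.trees import VascularTree

    t = VascularTree()
    for i, p in enumerate(positions):
        t.positions[i] = np.asarray(p, float)
    for i in range(len(positions) - 1):
        F = 1.0 if Fs is None else Fs[i]
        t.edges[(i, i + 1)] = _edge(i, i + 1, F,
                                    L=float(np.linalg.norm(
                                        t.positions[i + 1] - t.positions[i])),
                                    pa=t.positions[i], pb=t.positions[i + 1])
    return t


class TestPrune:
    def test_identity_with_trivial_thresholds(self):
        t = _chain_tree([(0, 0, 0), (3, 0, 0), (6, 0, 0)])
        out = prune(t, leaf_length_mm=0.0, geodesic_threshold=np.inf)
        assert set(out.edges) == set(t.edges)

    def test_short_terminal_branch_removed(self):
        # Y-tree: trunk plus a 3 mm terminal leaf; 5 mm threshold removes it
        from vesseltrees.trees import VascularTree

        t = VascularTree()
        pos = {0: (0, 0, 0), 1: (10, 0, 0), 2: (20, 0, 0), 3: (10, 3, 0)}
        for k, v in pos.items():
            t.positions[k] = np.array(v, float)
        for a, b in [(0, 1), (1, 2), (1, 3)]:
            L = float(np.linalg.norm(t.positions[b] - t.positions[a]))
            t.edges[(a, b)] = _edge(a, b, L, L=L, pa=t.positions[a], pb=t.positions[b])
        out = prune(t, leaf_length_mm=5.0)
        assert 3 not in out.positions
        assert (1, 3) not in out.edges
        assert (0, 1) in out.edges and (1, 2) in out.edges

    def test_leaf_pruning_never_disconnects_survivors(self, rng):
        g = _random_graph(rng, 8, 14)
        t = minimum_spanning_tree(g)
        if len(t.components()) != 1:
            return
        out = prune(t, leaf_length_mm=2.0)
        assert len(out.components()) <= 1 or out.n_nodes == 0

    def test_pruning_everything_warns(self):
        t = _chain_tree([(0, 0, 0), (1, 0, 0)])
        with pytest.warns(UserWarning):
            out = prune(t, leaf_length_mm=100.0)
        assert out.n_edges == 0


class TestRootTree:
    def test_path_graph_gives_a_parent_chain(self):
        t = root_tree(_chain_tree([(i, 0, 0) for i in range(5)]), 0)
        assert t.parent[0] is None
        assert all(t.parent[i] == i - 1 for i in range(1, 5))
        assert t.depth[4] == 4

    def test_children_counts_sum_to_n_minus_one(self, rng):
        g = _random_graph(rng, 7, 12)
        t = minimum_spanning_tree(g)
        comp = max(t.components(), key=len)
        sub = _induced(t, comp)
        rooted = root_tree(sub, min(comp))
        n_children = sum(1 for n, p in rooted.parent.items() if p is not None)
        assert n_children == len(comp) - 1

    def test_rerooting_preserves_edges(self):
        t = _chain_tree([(i, 0, 0) for i in range(4)])
        r0 = root_tree(t, 0)
        r3 = root_tree(t, 3)
        assert set(r0.edges) == set(r3.edges)

    def test_missing_root_rejected(self):
        with pytest.raises(ValueError):
            root_tree(_chain_tree([(0, 0, 0), (1, 0, 0)]), 99)


def _induced(tree, nodes):
    from vesseltrees.trees import VascularTree

    out = VascularTree()
    for n in nodes:
        out.positions[n] = tree.positions[n]
    for k, e in tree.edges.items():
        if k[0] in nodes and k[1] in nodes:
            out.edges[k] = e
    return out


class TestForestByROI:
    def _dumbbell(self):
        g = GeodesicGraph(nodes=[np.array([float(x), 5.0, 5.0])
                                 for x in (1, 3, 8, 10)])
        for a, b in [(0, 1), (1, 2), (2, 3)]:
            g.add_edge(_edge(a, b, 1.0, pa=g.nodes[a], pb=g.nodes[b]))
        return g

    def test_single_full_mask_equals_plain_mst(self):
        g = self._dumbbell()
        mask = Volume(np.ones((12, 12, 12)))
        forest = forest_by_roi(g, [mask])
        plain = minimum_spanning_tree(g)
        assert set(forest[0].edges) == set(plain.edges)

    def test_disjoint_masks_split_without_cross_edges(self):
        g = self._dumbbell()
        left = np.zeros((12, 12, 12))
        left[:6] = 1.0
        right = np.zeros((12, 12, 12))
        right[6:] = 1.0
        forest = forest_by_roi(g, [Volume(left), Volume(right)])
        assert sorted(forest[0].positions) == [0, 1]
        assert sorted(forest[1].positions) == [2, 3]
        assert (1, 2) not in forest[0].edges and (1, 2) not in forest[1].edges

    def test_fuzzy_membership_argmax_with_tie_to_lowest(self):
        g = self._dumbbell()
        m1 = Volume(np.full((12, 12, 12), 0.5))
        m2 = Volume(np.full((12, 12, 12), 0.5))
        forest = forest_by_roi(g, [m1, m2])
        assert sorted(forest[0].positions) == [0, 1, 2, 3]
        assert len(forest[1].positions) == 0
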