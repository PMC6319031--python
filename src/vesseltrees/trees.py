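"""Vascular tree extraction from the over-connected geodesic graph.

The vascular topology is the minimum spanning tree of the geodesic graph
under the integral geodesic length F.  Spurious terminal branches are
pruned by Euclidean length; rooting assigns the univocal parent-child
hierarchy; ROI masks split the graph into a forest of per-territory trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import GeodesicEdge, GeodesicGraph

__all__ = [
    "VascularTree",
    "kruskal_mst",
    "minimum_spanning_tree",
    "prune",
    "root_tree",
    "forest_by_roi",
]


@dataclass
class VascularTree:
    """A (forest of) acyclic vascular tree(s): nodes, edges, optional root."""

    positions: dict[int, np.ndarray] = field(default_factory=dict)  # mm
    edges: dict[tuple[int, int], GeodesicEdge] = field(default_factory=dict)
    root: int | None = None
    parent: dict[int, int | None] = field(default_factory=dict)
    depth: dict[int, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {n: [] for n in self.positions}
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def degrees(self) -> dict[int, int]:
        return {n: len(v) for n, v in self.neighbors().items()}

    def branchpoints(self) -> list[int]:
        return [n for n, d in self.degrees().items() if d >= 3]

    def endpoints(self) -> list[int]:
        return [n for n, d in self.degrees().items() if d == 1]

    def components(self) -> list[set[int]]:
        seen: set[int] = set()
        adj = self.neighbors()
        comps = []
        for n in sorted(self.positions):
            if n in seen:
                continue
            comp = {n}
            stack = [n]
            while stack:
                cur = stack.pop()
                for nb in adj[cur]:
                    if nb not in comp:
                        comp.add(nb)
                        stack.append(nb)
            seen |= comp
            comps.append(comp)
        return comps

    def centerline_polylines(self) -> list[np.ndarray]:
        out = []
        for key in sorted(self.edges):
            e = self.edges[key]
            out.append(e.path if e.path is not None and len(e.path) else
                       np.vstack([self.positions[key[0]], self.positions[key[1]]]))
        return out


def kruskal_mst(n_nodes: int, edges: list[GeodesicEdge]) -> list[GeodesicEdge]:
    """Deterministic Kruskal MST: ties broken by (F, smaller id, larger id)."""
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[GeodesicEdge] = []
    ordered = sorted(edges, key=lambda e: (e.F, min(e.a, e.b), max(e.a, e.b)))
    for e in ordered:
        ra, rb = find(e.a), find(e.b)
        if ra != rb:
            parent[ra] = rb
            chosen.append(e)
    return chosen


def minimum_spanning_tree(graph: GeodesicGraph) -> VascularTree:
    """MST (or per-component forest) of the over-connected graph under F."""
    tree = VascularTree()
    if not graph.nodes:
        return tree
    mst = kruskal_mst(len(graph.nodes), graph.edge_list())
    for n in range(len(graph.nodes)):
        tree.positions[n] = np.asarray(graph.nodes[n], dtype=float)
    for e in mst:
        tree.edges[(min(e.a, e.b), max(e.a, e.b))] = e
    return tree


def _branch_chain(tree: VascularTree, leaf: int, adj) -> list[int]:
    """Walk from a leaf through degree-2 nodes up to the first junction."""
    chain = [leaf]
    prev = None
    cur = leaf
    while True:
        nxt = [n for n in adj[cur] if n != prev]
        if len(nxt) != 1:
            break
        prev, cur = cur, nxt[0]
        chain.append(cur)
        if len(adj[cur]) != 2:
            break
    return chain


def prune(
    tree: VascularTree,
    leaf_length_mm: float = 5.0,
    geodesic_threshold: float = np.inf,
) -> VascularTree:
    """Remove short terminal branches and over-costly geodesic edges.

    Terminal branches whose cumulative Euclidean length is below the leaf
    threshold are removed iteratively until stable; edges with F above the
    geodesic threshold are dropped afterwards (possibly splitting the tree
    into a forest).
    """
    out = VascularTree(positions=dict(tree.positions), edges=dict(tree.edges))
    changed = True
    while changed:
        changed = False
        adj = out.neighbors()
        leaves = [n for n, nb in adj.items() if len(nb) == 1]
        for leaf in leaves:
            if leaf not in out.positions or len(adj.get(leaf, [])) != 1:
                continue
            chain = _branch_chain(out, leaf, adj)
            Ls = 0.0
            for a, b in zip(chain[:-1], chain[1:]):
                Ls += out.edges[(min(a, b), max(a, b))].L
            if Ls < leaf_length_mm:
                for a, b in zip(chain[:-1], chain[1:]):
                    out.edges.pop((min(a, b), max(a, b)), None)
                for n in chain[:-1]:
                    out.positions.pop(n, None)
                changed = True
                adj = out.neighbors()
    if np.isfinite(geodesic_threshold):
        for key in [k for k, e in out.edges.items() if e.F > geodesic_threshold]:
            out.edges.pop(key)
        connected = {n for k in out.edges for n in k}
        isolated = set(out.positions) - connected
        if len(out.positions) > 1:
            for n in isolated:
                out.positions.pop(n)
    if not out.positions or (tree.n_edges > 0 and out.n_edges == 0):
        warnings.warn("pruning removed the entire tree")
    return out


def root_tree(tree: VascularTree, root: int) -> VascularTree:
    """Assign the parent-child hierarchy by breadth-first search from root."""
    if root not in tree.positions:
        raise ValueError(f"root node {root} is not in the tree")
    out = VascularTree(positions=dict(tree.positions), edges=dict(tree.edges))
    adj = out.neighbors()
    parent: dict[int, int | None] = {root: None}
    depth = {root: 0}
    queue = [root]
    while queue:
        cur = queue.pop(0)
        for nb in sorted(adj[cur]):
            if nb not in parent:
                parent[nb] = cur
                depth[nb] = depth[cur] + 1
                queue.append(nb)
    out.root = root
    out.parent = parent
    out.depth = depth
    return out


def forest_by_roi(
    graph: GeodesicGraph,
    masks: list,
) -> list[VascularTree]:
    """Partition nodes by (fuzzy) mask membership and extract per-ROI MSTs.

    Each node is assigned to the mask with maximal membership at its
    position (ties to the lowest mask index); nodes in no mask are treated
    as background and excluded.  Each ROI's MST is computed on the induced
    subgraph.
    """
    if not masks:
        return [minimum_spanning_tree(graph)]
    n = len(graph.nodes)
    member = np.full(n, -1, dtype=int)
    scores = np.zeros((n, len(masks)))
    for mi, mask in enumerate(masks):
        vox = mask.world_to_voxel(np.array(graph.nodes)) if n else np.empty((0, 3))
        from scipy import ndimage

        scores[:, mi] = ndimage.map_coordinates(
            mask.data.astype(float), vox.T, order=1, mode="constant", cval=0.0
        )
    has = scores.max(axis=1) > 0
    member[has] = np.argmax(scores[has], axis=1)  # argmax takes lowest on ties
    forest = []
    for mi in range(len(masks)):
        ids = sorted(np.nonzero(member == mi)[0])
        sub = GeodesicGraph(nodes=list(graph.nodes))
        for (i, j), e in graph.edges.items():
            if member[i] == mi and member[j] == mi:
                sub.edges[(i, j)] = e
        tree = VascularTree()
        mst = kruskal_mst(len(sub.nodes), sub.edge_list())
        for nid in ids:
            tree.positions[nid] = np.asarray(graph.nodes[nid], dtype=float)
        for e in mst:
            tree.edges[(min(e.a, e.b), max(e.a, e.b))] = e
        forest.append(tree)
    return forest
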