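"""Spatially- and topologically-aware evaluation of reconstructed trees.

Geometric accuracy uses symmetric centerline distances (mean and 95th
percentile Hausdorff); topology uses branchpoint detection within a spatial
neighbourhood, the ordered tree edit distance and its normalized overlap
index, and a DIADEM-style score that couples spatial node matching with
ancestor connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic import GroundTruth
from .trees import VascularTree

__all__ = [
    "TreeComparison",
    "centerline_errors",
    "branchpoint_detection",
    "tree_edit_distance",
    "ted_overlap",
    "diadem_score",
    "compare",
]


@dataclass
class TreeComparison:
    epsilon_s: float
    epsilon_h: float
    bp_detection_rate: float
    bp_epsilon_s: float
    bp_epsilon_h: float
    ted_ov: float | None = None
    diadem: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# centerline geometry

def resample_polyline(path: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at a fixed arclength step (keeps both endpoints)."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return path
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return path[:1]
    s = np.linspace(0.0, cum[-1], max(int(np.ceil(cum[-1] / step)) + 1, 2))
    return np.column_stack([np.interp(s, cum, path[:, d]) for d in range(3)])


def _polyline_cloud(polylines, step: float) -> np.ndarray:
    pts = [resample_polyline(p, step) for p in polylines if len(p) > 0]
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def _as_polylines(obj) -> list:
    if isinstance(obj, VascularTree):
        return obj.centerline_polylines()
    if isinstance(obj, GroundTruth):
        return obj.centerlines
    return list(obj)


def centerline_errors(reconstructed, truth, sampling_step: float = 0.5):
    """Mean symmetric distance and mean directed 95th-percentile Hausdorff.

    Both centerline sets are resampled at the given step; returns
    ``(epsilon_s, epsilon_h)`` in mm, or infinities when one side is empty.
    """
    a = _polyline_cloud(_as_polylines(reconstructed), sampling_step)
    b = _polyline_cloud(_as_polylines(truth), sampling_step)
    if len(a) == 0 or len(b) == 0:
        return float("inf"), float("inf")
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    eps_s = float(np.concatenate([d_ab, d_ba]).mean())
    eps_h = float((np.percentile(d_ab, 95) + np.percentile(d_ba, 95)) / 2.0)
    return eps_s, eps_h


# ---------------------------------------------------------------------------
# branchpoints

def _tree_branchpoint_positions(tree) -> np.ndarray:
    if isinstance(tree, VascularTree):
        ids = tree.branchpoints()
        return np.array([tree.positions[i] for i in ids]).reshape(-1, 3)
    if isinstance(tree, GroundTruth):
        return tree.branchpoints
    return np.asarray(tree, dtype=float).reshape(-1, 3)


def greedy_match(
    truth_pts: np.ndarray, recon_pts: np.ndarray, tolerance: float
) -> list[tuple[int, int, float]]:
    """One-to-one matching by ascending distance, rejecting beyond tolerance."""
    if len(truth_pts) == 0 or len(recon_pts) == 0:
        return []
    d = np.linalg.norm(truth_pts[:, None, :] - recon_pts[None, :, :], axis=-1)
    order = np.argsort(d, axis=None, kind="stable")
    used_t: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for flat in order:
        ti, ri = np.unravel_index(flat, d.shape)
        if d[ti, ri] > tolerance:
            break
        if ti in used_t or ri in used_r:
            continue
        used_t.add(int(ti))
        used_r.add(int(ri))
        matches.append((int(ti), int(ri), float(d[ti, ri])))
    return matches


def branchpoint_detection(reconstructed, truth, tolerance: float = 5.0):
    """Detection rate and errors of truth branchpoints within the tolerance."""
    t = _tree_branchpoint_positions(truth)
    r = _tree_branchpoint_positions(reconstructed)
    if len(t) == 0:
        raise ValueError("truth has no branchpoints")
    if len(r) == 0:
        return 0.0, float("inf"), float("inf")
    matches = greedy_match(t, r, tolerance)
    rate = len(matches) / len(t)
    if not matches:
        return 0.0, float("inf"), float("inf")
    dists = np.array([m[2] for m in matches])
    return float(rate), float(dists.mean()), float(np.percentile(dists, 95))


# ---------------------------------------------------------------------------
# ordered tree edit distance (Zhang-Shasha) and the overlap index

def _canonical_children(tree: VascularTree) -> dict[int, list[int]]:
    """Deterministic child ordering: subtree size, then branch azimuth."""
    if tree.root is None or not tree.parent:
        raise ValueError("tree must be rooted")
    children: dict[int, list[int]] = {n: [] for n in tree.positions}
    for n, p in tree.parent.items():
        if p is not None:
            children[p].append(n)

    size: dict[int, int] = {}

    def _size(n: int) -> int:
        size[n] = 1 + sum(_size(c) for c in children[n])
        return size[n]

    _size(tree.root)

    def _azimuth(n: int) -> tuple[float, float]:
        p = tree.parent[n]
        v = tree.positions[n] - tree.positions[p] if p is not None else np.zeros(3)
        return (float(np.arctan2(v[1], v[0])), float(v[2]))

    for n in children:
        children[n].sort(key=lambda c: (size[c], _azimuth(c)))
    return children


def _postorder(root: int, children: dict[int, list[int]]):
    """Postorder node list and leftmost-leaf indices (iterative)."""
    order: list[int] = []
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
        else:
            stack.append((node, True))
            for c in reversed(children[node]):
                stack.append((c, False))
    index = {n: i for i, n in enumerate(order)}
    lml = np.empty(len(order), dtype=int)
    for i, n in enumerate(order):
        cur = n
        while children[cur]:
            cur = children[cur][0]
        lml[i] = index[cur]
    return order, lml


def tree_edit_distance(tree_a: VascularTree, tree_b: VascularTree) -> int:
    """Unit-cost insert/delete edit distance between rooted ordered trees.

    Nodes are unlabeled (relabel cost 0); child order is canonicalized, so
    isomorphic trees have distance 0.
    """
    ca = _canonical_children(tree_a)
    cb = _canonical_children(tree_b)
    oa, la = _postorder(tree_a.root, ca)
    ob, lb = _postorder(tree_b.root, cb)
    return int(_zhang_shasha(la, lb))


def _keyroots(lml: np.ndarray) -> list[int]:
    seen: dict[int, int] = {}
    for i in range(len(lml)):
        seen[int(lml[i])] = i
    return sorted(seen.values())


def _zhang_shasha(la: np.ndarray, lb: np.ndarray) -> float:
    m, n = len(la), len(lb)
    td = np.zeros((m, n))
    for i in _keyroots(la):
        for j in _keyroots(lb):
            _treedist(i, j, la, lb, td)
    return td[m - 1, n - 1]


def _treedist(i: int, j: int, la, lb, td) -> None:
    li, lj = la[i], lb[j]
    fd = np.zeros((i - li + 2, j - lj + 2))
    fd[1:, 0] = np.arange(1, i - li + 2)  # delete
    fd[0, 1:] = np.arange(1, j - lj + 2)  # insert
    for di in range(1, i - li + 2):
        for dj in range(1, j - lj + 2):
            gi = li + di - 1
            gj = lj + dj - 1
            if la[gi] == li and lb[gj] == lj:
                fd[di, dj] = min(
                    fd[di - 1, dj] + 1,
                    fd[di, dj - 1] + 1,
                    fd[di - 1, dj - 1],  # relabel cost 0
                )
                td[gi, gj] = fd[di, dj]
            else:
                fd[di, dj] = min(
                    fd[di - 1, dj] + 1,
                    fd[di, dj - 1] + 1,
                    fd[la[gi] - li, lb[gj] - lj] + td[gi, gj],
                )


def ted_overlap(tree_a: VascularTree, tree_b: VascularTree) -> float:
    """Normalized tree-overlap index on the unit scale: 1 for isomorphic trees.

    ``1 - TED(a, b) / (TED(a, {}) + TED(b, {}))`` where the edit distance to
    the void tree is the node count.
    """
    ted = tree_edit_distance(tree_a, tree_b)
    denom = tree_a.n_nodes + tree_b.n_nodes
    if denom == 0:
        return 1.0
    return 1.0 - ted / denom


# ---------------------------------------------------------------------------
# DIADEM-style spatially-aware score

def _critical_nodes(tree: VascularTree) -> tuple[list[int], dict[int, float]]:
    """Branchpoints and terminals with subtree-degree weights.

    A terminal weighs 1; a branchpoint weighs the number of terminal leaves
    in its subtree.  The root contributes its branchpoint weight if it
    branches, else it only anchors connectivity (weight 0).
    """
    deg = tree.degrees()
    children: dict[int, list[int]] = {n: [] for n in tree.positions}
    for n, p in tree.parent.items():
        if p is not None:
            children[p].append(n)

    leaves_below: dict[int, int] = {}

    def _count(n: int) -> int:
        if not children[n]:
            leaves_below[n] = 1
        else:
            leaves_below[n] = sum(_count(c) for c in children[n])
        return leaves_below[n]

    _count(tree.root)
    crit = []
    weights = {}
    for n in tree.positions:
        if n == tree.root:
            w = float(leaves_below[n]) if deg[n] >= 3 else 0.0
            crit.append(n)
            weights[n] = w
        elif deg[n] >= 3 or deg[n] == 1:
            crit.append(n)
            weights[n] = float(leaves_below[n]) if deg[n] >= 3 else 1.0
    return crit, weights


def diadem_score(
    reconstructed: VascularTree, truth: VascularTree, xy_tolerance: float = 5.0
) -> float:
    """Fraction of truth branch/terminal weight matched in space and topology.

    A truth node is matched when a reconstructed node lies within the spatial
    tolerance and is a descendant (in the reconstructed hierarchy) of the
    node matched to its nearest matched truth ancestor.  Weights follow the
    subtree degree, so missing a large subtree costs proportionally more.
    """
    if truth.root is None or reconstructed.root is None:
        raise ValueError("both trees must be rooted")
    if truth.n_nodes == 0:
        raise ValueError("truth tree is empty")
    crit, weights = _critical_nodes(truth)
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("truth tree has no branch or terminal structure")

    r_ids = sorted(reconstructed.positions)
    r_pos = np.array([reconstructed.positions[i] for i in r_ids])

    def recon_ancestors(r: int) -> set[int]:
        out = set()
        cur = r
        while cur is not None:
            out.add(cur)
            cur = reconstructed.parent.get(cur)
        return out

    # truth nodes in BFS (depth) order so ancestors are decided first
    order = sorted(crit, key=lambda n: truth.depth.get(n, 0))
    match: dict[int, int] = {}
    matched_weight = 0.0
    for n in order:
        p = truth.positions[n]
        d = np.linalg.norm(r_pos - p, axis=1)
        cand = np.argsort(d, kind="stable")
        # nearest matched truth ancestor
        anc = truth.parent.get(n)
        anc_match = None
        while anc is not None:
            if anc in match:
                anc_match = match[anc]
                break
            anc = truth.parent.get(anc)
        for ci in cand:
            if d[ci] > xy_tolerance:
                break
            r = r_ids[int(ci)]
            if anc_match is not None and anc_match not in recon_ancestors(r):
                continue
            match[n] = r
            matched_weight += weights[n]
            break
    return matched_weight / total


def compare(
    reconstructed: VascularTree,
    truth: GroundTruth,
    bp_tolerance: float = 5.0,
    sampling_step: float = 0.5,
    with_topology: bool = True,
) -> TreeComparison:
    """Full geometric and topological comparison against ground truth."""
    eps_s, eps_h = centerline_errors(reconstructed, truth, sampling_step)
    rate, bps, bph = branchpoint_detection(reconstructed, truth, bp_tolerance)
    ted_ov = dia = None
    if with_topology and reconstructed.root is not None:
        gt_tree = truth.to_tree()
        ted_ov = ted_overlap(reconstructed, gt_tree)
        dia = diadem_score(reconstructed, gt_tree, bp_tolerance)
    return TreeComparison(
        epsilon_s=eps_s,
        epsilon_h=eps_h,
        bp_detection_rate=rate,
        bp_epsilon_s=bps,
        bp_epsilon_h=bph,
        ted_ov=ted_ov,
        diadem=dia,
    )
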