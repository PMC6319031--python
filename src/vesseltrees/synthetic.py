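"""Synthetic vascular trees: random bifurcating phantoms with exact truth.

Random acyclic trees are grown by recursive bifurcation with smoothly
wandering branch trajectories, rasterized as tubes with per-generation
decaying radii into an isotropic volume (foreground 1, background 0, optional
partial-volume blur and additive Gaussian noise).  The exact centerlines,
branchpoints, endpoints and parent hierarchy are retained as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .connectivity import GeodesicEdge
from .scalespace import Volume
from .trees import VascularTree, root_tree

__all__ = [
    "SyntheticTreeSpec",
    "GroundTruth",
    "generate_tree",
    "straight_tube_phantom",
    "NOISE_LEVELS",
]

# the three increasing degradation levels used across the synthetic study,
# as fractions of the unit foreground intensity
NOISE_LEVELS = (0.05, 0.15, 0.30)


@dataclass(frozen=True)
class SyntheticTreeSpec:
    terminal_branches: int = 10
    volume_shape: tuple[int, int, int] = (128, 128, 128)
    radius_root: float = 2.0          # mm
    radius_decay: float = 0.8         # per generation
    noise_sigma: float = 0.0          # additive Gaussian, foreground = 1
    rng_seed: int = 0
    branch_length: float = 22.0       # mm at the root generation
    length_decay: float = 0.85
    min_length: float = 7.0           # mm
    curvature: float = 0.06           # per-mm random heading change
    blur_sigma: float = 0.5           # voxels of partial-volume smoothing
    avoid_mm: float = 4.0             # minimum approach between branches

    def __post_init__(self) -> None:
        if self.terminal_branches < 1:
            raise ValueError("terminal_branches must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Exact centerline geometry and topology of a synthetic tree."""

    node_positions: dict[int, np.ndarray]           # mm
    parent: dict[int, int | None]
    edge_paths: dict[tuple[int, int], np.ndarray]   # (a, b) with a = parent
    root: int = 0
    branch_radii: dict = field(default_factory=dict)  # mm per edge

    def _degrees(self) -> dict[int, int]:
        deg = {n: 0 for n in self.node_positions}
        for a, b in self.edge_paths:
            deg[a] += 1
            deg[b] += 1
        return deg

    @property
    def branchpoints(self) -> np.ndarray:
        deg = self._degrees()
        ids = sorted(n for n, d in deg.items() if d >= 3)
        return np.array([self.node_positions[n] for n in ids]).reshape(-1, 3)

    @property
    def endpoints(self) -> np.ndarray:
        deg = self._degrees()
        ids = sorted(n for n, d in deg.items() if d == 1)
        return np.array([self.node_positions[n] for n in ids]).reshape(-1, 3)

    @property
    def terminal_leaves(self) -> np.ndarray:
        deg = self._degrees()
        ids = sorted(n for n, d in deg.items() if d == 1 and n != self.root)
        return np.array([self.node_positions[n] for n in ids]).reshape(-1, 3)

    @property
    def centerlines(self) -> list[np.ndarray]:
        return [self.edge_paths[k] for k in sorted(self.edge_paths)]

    def to_tree(self) -> VascularTree:
        tree = VascularTree()
        for n, p in self.node_positions.items():
            tree.positions[n] = np.asarray(p, dtype=float)
        for (a, b), path in self.edge_paths.items():
            L = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
            tree.edges[(min(a, b), max(a, b))] = GeodesicEdge(
                a=a, b=b, path=path, F=L, L=L
            )
        return root_tree(tree, self.root)


def _rng_unit_perp(rng: np.random.Generator, d: np.ndarray) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v = v - (v @ d) * d
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1.0 - np.cos(angle))
    )


def _grow_branch(
    rng, start, direction, length, extent, margin, curvature,
    occupied=None, avoid_mm: float = 4.0,
):
    """1 mm stepped trajectory with random curvature, steered off walls.

    ``occupied`` (n, 3) holds centerline points of previously grown
    branches; the walker is repelled whenever it comes within ``avoid_mm``
    of them (ignoring those near its own start, where siblings legitimately
    share the bifurcation), emulating the non-self-approaching geometry of
    space-filling vascular beds and avoiding kissing-vessel artifacts in
    the phantom itself.
    """
    pts = [start.copy()]
    d = direction / np.linalg.norm(direction)
    p = start.copy()
    n_steps = max(int(round(length)), 2)
    if occupied is not None and len(occupied):
        occ = occupied[np.linalg.norm(occupied - start, axis=1) > 5.0]
    else:
        occ = np.empty((0, 3))
    min_clear = np.inf
    for _ in range(n_steps):
        d = d + curvature * rng.normal(size=3)
        # inward pull near the boundary
        low = p - margin
        high = extent - margin - p
        push = np.where(low < 0, -low, 0.0) + np.where(high < 0, high, 0.0)
        d = d + 0.3 * push
        if len(occ):
            delta = p - occ
            dist = np.linalg.norm(delta, axis=1)
            k = int(np.argmin(dist))
            min_clear = min(min_clear, float(dist[k]))
            if dist[k] < avoid_mm + 2.0:
                away = delta[k] / max(dist[k], 1e-6)
                d = d + 1.5 * (avoid_mm + 2.0 - dist[k]) / avoid_mm * away
                if dist[k] < 0.75 * avoid_mm and (d @ away) < 0:
                    # heading into the obstacle: keep only the tangent part
                    d = d - (d @ away) * away
        d /= np.linalg.norm(d)
        p = p + d
        p = np.clip(p, 1.0, extent - 1.0)
        pts.append(p.copy())
    return np.array(pts), d, min_clear


def generate_tree(spec: SyntheticTreeSpec) -> tuple[GroundTruth, Volume]:
    """Grow, rasterize and degrade one random vascular tree.

    The geometry is regrown from derived random substreams when branches
    approach each other too closely; the attempt with the widest minimum
    separation wins, so non-adjacent branches keep a clear gap as in
    space-filling vascular phantoms.
    """
    best = None
    for attempt in range(5):
        gt, sep = _grow_tree_geometry(spec, attempt)
        if best is None or sep > best[1]:
            best = (gt, sep)
        if sep >= 0.9 * spec.avoid_mm:
            break
    gt = best[0]
    return gt, _render_tree(spec, gt)


def _interior_separation(gt: GroundTruth, exclusion: float = 5.0) -> float:
    """Minimum distance between non-adjacent stretches of the centerlines."""
    from scipy.spatial import cKDTree

    paths = {k: _densify(p, 0.5) for k, p in gt.edge_paths.items()}
    out = np.inf
    for k, p in paths.items():
        others = [q for k2, q in paths.items() if k2 != k]
        if not others:
            continue
        kd = cKDTree(np.vstack(others))
        d = kd.query(p)[0]
        da = np.linalg.norm(p - p[0], axis=1)
        db = np.linalg.norm(p - p[-1], axis=1)
        interior = (da > exclusion) & (db > exclusion)
        if interior.any():
            out = min(out, float(d[interior].min()))
    return out


def _grow_tree_geometry(spec: SyntheticTreeSpec, attempt: int):
    shape = np.asarray(spec.volume_shape, dtype=int)
    capacity = int(np.prod(shape) // 8000)
    if spec.terminal_branches > max(capacity, 1):
        raise ValueError(
            f"volume {tuple(shape)} too small for {spec.terminal_branches} "
            f"terminal branches (capacity {capacity})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, attempt]))
    extent = shape.astype(float) - 1.0
    margin = 4.0

    root_pos = np.array(
        [margin, extent[1] / 2 + rng.uniform(-5, 5), extent[2] / 2 + rng.uniform(-5, 5)]
    )
    root_dir = np.array([1.0, 0.0, 0.0])

    nodes: dict[int, np.ndarray] = {0: root_pos}
    parent: dict[int, int | None] = {0: None}
    edge_paths: dict[tuple[int, int], np.ndarray] = {}
    branches: list[tuple[np.ndarray, float]] = []  # (polyline, radius)
    next_id = [1]

    occupied: list[np.ndarray] = []

    def grow(node_id: int, direction: np.ndarray, gen: int, n_term: int) -> None:
        length = max(spec.branch_length * spec.length_decay**gen, spec.min_length)
        radius = max(spec.radius_root * spec.radius_decay**gen, 0.8)
        occ = np.vstack(occupied) if occupied else np.empty((0, 3))
        best = None
        for _ in range(6):  # retry with fresh randomness on near-collisions
            path, end_dir, clear = _grow_branch(
                rng, nodes[node_id], direction, length, extent, margin,
                spec.curvature, occupied=occ, avoid_mm=spec.avoid_mm,
            )
            if best is None or clear > best[2]:
                best = (path, end_dir, clear)
            if clear >= 0.8 * spec.avoid_mm:
                break
        path, end_dir, _ = best
        child = next_id[0]
        next_id[0] += 1
        nodes[child] = path[-1].copy()
        parent[child] = node_id
        edge_paths[(node_id, child)] = path
        branches.append((path, radius))
        occupied.append(path)
        if n_term == 1:
            return
        n1 = n_term // 2
        n2 = n_term - n1
        if rng.random() < 0.5:
            n1, n2 = n2, n1
        axis = _rng_unit_perp(rng, end_dir)
        ang1 = np.deg2rad(rng.uniform(30, 55))
        ang2 = np.deg2rad(rng.uniform(30, 55))
        grow(child, _rotate(end_dir, axis, ang1), gen + 1, n1)
        grow(child, _rotate(end_dir, axis, -ang2), gen + 1, n2)

    grow(0, root_dir, 0, spec.terminal_branches)
    gt = GroundTruth(node_positions=nodes, parent=parent, edge_paths=edge_paths)
    gt.branch_radii = {  # per-edge radii for rendering
        k: max(spec.radius_root * spec.radius_decay**_gen_of(parent, k[1]), 0.8)
        for k in edge_paths
    }
    return gt, _interior_separation(gt)


def _gen_of(parent: dict, node: int) -> int:
    g = -1
    cur: int | None = node
    while cur is not None:
        cur = parent.get(cur)
        g += 1
    return g


def _render_tree(spec: SyntheticTreeSpec, gt: GroundTruth) -> Volume:
    shape = tuple(int(s) for s in spec.volume_shape)
    branches = [(p, gt.branch_radii[k]) for k, p in gt.edge_paths.items()]
    vol = _rasterize(branches, shape)
    if spec.blur_sigma > 0:
        vol = ndimage.gaussian_filter(vol, spec.blur_sigma)
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.rng_seed, 977])
        )
        vol = vol + noise_rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    return Volume(vol.astype(np.float32), np.eye(4))


def _rasterize(branches, shape) -> np.ndarray:
    """Union of tubes: one distance transform per distinct radius."""
    out = np.zeros(shape, dtype=np.float32)
    by_radius: dict[float, list[np.ndarray]] = {}
    for path, radius in branches:
        by_radius.setdefault(round(float(radius), 3), []).append(path)
    for radius, paths in by_radius.items():
        marks = np.zeros(shape, dtype=bool)
        for path in paths:
            dense = _densify(path, 0.25)
            idx = np.round(dense).astype(int)
            idx = np.clip(idx, 0, np.asarray(shape) - 1)
            marks[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        dist = ndimage.distance_transform_edt(~marks)
        out[dist <= radius] = 1.0
    return out


def _densify(path: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return path
    s = np.arange(0.0, cum[-1] + step / 2, step)
    return np.column_stack(
        [np.interp(s, cum, path[:, d]) for d in range(3)]
    )


def straight_tube_phantom(
    length: float,
    radius: float,
    direction=(1.0, 0.0, 0.0),
    shape=(64, 64, 64),
    blur_sigma: float = 0.0,
) -> tuple[GroundTruth, Volume]:
    """A single straight tube through the volume center, exact centerline."""
    shape = np.asarray(shape, dtype=int)
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    center = (shape - 1) / 2.0
    a = center - d * length / 2.0
    b = center + d * length / 2.0
    if np.any(a < 0) or np.any(b < 0) or np.any(a > shape - 1) or np.any(b > shape - 1):
        raise ValueError("tube does not fit in the volume")

    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )
    ap = grid - a
    t = np.clip((ap @ d) / length, 0.0, 1.0) * length
    closest = a + t[..., None] * d
    dist = np.linalg.norm(grid - closest, axis=-1)
    vol = (dist <= radius).astype(np.float32)
    if blur_sigma > 0:
        vol = ndimage.gaussian_filter(vol, blur_sigma)

    n_pts = max(int(round(length)) + 1, 2)
    path = a + np.linspace(0, 1, n_pts)[:, None] * (b - a)
    gt = GroundTruth(
        node_positions={0: a, 1: b},
        parent={0: None, 1: 0},
        edge_paths={(0, 1): path},
    )
    return gt, Volume(vol, np.eye(4))
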