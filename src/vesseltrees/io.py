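"""Readers and writers: NIfTI volumes, SWC / GraphML trees, reports."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np

from .connectivity import GeodesicEdge, GeodesicGraph
from .multiscale import RiemannianPotential
from .scalespace import Volume
from .trees import VascularTree, root_tree

__all__ = [
    "read_volume",
    "write_volume",
    "write_potential",
    "export_tree",
    "read_swc",
    "read_graphml",
    "export_graph",
    "write_report",
]


def read_volume(path) -> Volume:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavours
        raise IOError(f"cannot read NIfTI volume from {path}: {exc}") from exc
    return Volume(np.asarray(img.get_fdata(), dtype=np.float32), img.affine)


def write_volume(volume: Volume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume.data), volume.affine), str(path))


def write_potential(potential: RiemannianPotential, out_dir, stem: str = "potential"):
    """CVM as a 3D NIfTI and TF as a 6-volume 4D NIfTI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cvm_path = out_dir / f"{stem}_cvm.nii.gz"
    tf_path = out_dir / f"{stem}_tf.nii.gz"
    nib.save(nib.Nifti1Image(potential.cvm.astype(np.float32), potential.affine),
             str(cvm_path))
    nib.save(nib.Nifti1Image(potential.tf.astype(np.float32), potential.affine),
             str(tf_path))
    return cvm_path, tf_path


def export_tree(tree: VascularTree, path, fmt: str = "swc") -> None:
    """Write a tree as SWC (rooted, parents precede children) or GraphML."""
    path = Path(path)
    if fmt == "swc":
        if tree.root is None or not tree.parent:
            raise ValueError("SWC export requires a rooted tree")
        order = sorted(tree.positions, key=lambda n: tree.depth.get(n, 0))
        swc_id = {n: i + 1 for i, n in enumerate(order)}
        lines = []
        for n in order:
            x, y, z = tree.positions[n]
            p = tree.parent.get(n)
            pid = -1 if p is None else swc_id[p]
            lines.append(f"{swc_id[n]} 3 {x:.6f} {y:.6f} {z:.6f} 1.0 {pid}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        nx.write_graphml(_to_networkx(tree), str(path))
    else:
        raise ValueError(f"unknown tree format: {fmt}")


def _to_networkx(tree: VascularTree) -> nx.Graph:
    g = nx.Graph()
    for n, p in tree.positions.items():
        g.add_node(int(n), x=float(p[0]), y=float(p[1]), z=float(p[2]))
    for (i, j), e in tree.edges.items():
        g.add_edge(int(i), int(j), F=float(e.F), L=float(e.L))
    return g


def read_swc(path) -> VascularTree:
    tree = VascularTree()
    parent_of: dict[int, int] = {}
    root = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, _, x, y, z, _, pid = line.split()[:7]
        sid, pid = int(sid), int(pid)
        tree.positions[sid] = np.array([float(x), float(y), float(z)])
        if pid == -1:
            root = sid
        else:
            if pid not in tree.positions:
                raise ValueError("SWC parent id references a later row")
            parent_of[sid] = pid
            path_arr = np.vstack([tree.positions[pid], tree.positions[sid]])
            L = float(np.linalg.norm(path_arr[1] - path_arr[0]))
            tree.edges[(min(sid, pid), max(sid, pid))] = GeodesicEdge(
                a=pid, b=sid, path=path_arr, F=L, L=L
            )
    if root is None:
        raise ValueError("SWC file has no root row")
    return root_tree(tree, root)


def read_graphml(path) -> VascularTree:
    g = nx.read_graphml(str(path))
    tree = VascularTree()
    for n, d in g.nodes(data=True):
        tree.positions[int(n)] = np.array([float(d["x"]), float(d["y"]), float(d["z"])])
    for i, j, d in g.edges(data=True):
        i, j = int(i), int(j)
        a, b = min(i, j), max(i, j)
        p = np.vstack([tree.positions[a], tree.positions[b]])
        tree.edges[(a, b)] = GeodesicEdge(
            a=a, b=b, path=p, F=float(d.get("F", 0.0)), L=float(d.get("L", 0.0))
        )
    return tree


def export_graph(graph: GeodesicGraph, path, paths_sidecar=None) -> None:
    """GraphML for the over-connected graph plus a JSON polyline sidecar."""
    g = nx.Graph()
    for i, p in enumerate(graph.nodes):
        g.add_node(i, x=float(p[0]), y=float(p[1]), z=float(p[2]))
    for (i, j), e in graph.edges.items():
        g.add_edge(i, j, F=float(e.F), L=float(e.L))
    nx.write_graphml(g, str(path))
    if paths_sidecar is not None:
        payload = {
            f"{i}-{j}": e.path.tolist() for (i, j), e in sorted(graph.edges.items())
        }
        Path(paths_sidecar).write_text(json.dumps(payload))


def write_report(report: dict, path) -> None:
    def _clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    Path(path).write_text(json.dumps(_clean(report), indent=2))
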