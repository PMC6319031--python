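"""Discrete 3D orientation sets: icosphere bases and basis completion.

Second-derivative kernels respond identically along antipodal directions,
so icosphere vertices are deduplicated to one hemisphere before each
direction is completed to a right-handed orthonormal basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = ["OrientationSet", "icosphere_bases", "complete_basis"]


@dataclass
class OrientationSet:
    """A list of 3x3 orthonormal bases (det +1) with a provenance tag."""

    bases: list[np.ndarray]
    source: str  # "icosphere" or "data-driven"

    def __len__(self) -> int:
        return len(self.bases)

    def directions(self) -> np.ndarray:
        """First axes of the bases, shape (n, 3)."""
        return np.array([b[:, 0] for b in self.bases])


def icosphere_vertices(subdivision_level: int) -> np.ndarray:
    """Unit vertices of a subdivided icosahedron (10*4^n + 2 of them)."""
    if subdivision_level < 0:
        raise ValueError("subdivision level must be >= 0")
    mesh = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    return np.asarray(mesh.vertices, dtype=float)


def _dedup_antipodal(dirs: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    kept: list[np.ndarray] = []
    for d in dirs:
        if any(abs(abs(d @ k) - 1.0) < tol for k in kept):
            continue
        # canonical hemisphere: first non-negligible component positive
        for comp in d:
            if abs(comp) > tol:
                if comp < 0:
                    d = -d
                break
        kept.append(d)
    return np.array(kept)


def icosphere_bases(subdivision_level: int = 2) -> OrientationSet:
    """Orthonormal bases from icosphere vertices, antipodally deduplicated."""
    dirs = _dedup_antipodal(icosphere_vertices(subdivision_level))
    return OrientationSet(
        bases=[complete_basis(d) for d in dirs], source="icosphere"
    )


def complete_basis(direction) -> np.ndarray:
    """Deterministic right-handed basis with the given unit first column.

    The second axis is the canonical axis least aligned with the direction,
    Gram-Schmidt orthogonalized; the third closes the right-handed triad.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("direction must be a non-zero vector")
    d = d / n
    e = np.zeros(3)
    e[int(np.argmin(np.abs(d)))] = 1.0
    v = e - (e @ d) * d
    v /= np.linalg.norm(v)
    w = np.cross(d, v)
    return np.column_stack([d, v, w])
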