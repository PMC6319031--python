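"""Anisotropic fast marching over the Riemannian vesselness potential.

Solves the Eikonal boundary-value problem |grad U| = 1, U(source) = 0 with
front speed proportional to the scalar vesselness and an anisotropic local
norm from the unit-determinant tensor field: the traversal cost per mm along
unit direction d at voxel x is sqrt(d^t TF(x) d) / (CVM(x) + eps_floor).

The solver is an ordered-upwind scheme on the 26-neighbourhood: each
narrow-band update minimizes the interpolated arrival time over the
triangulated cube surface around the voxel, using the closed-form minimum
along every surface edge (pairs of neighbours sharing a cube face).  When a
later update improves an already-accepted voxel beyond tolerance the voxel
is re-opened (recursive correction), which keeps the scheme convergent for
strongly anisotropic metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["EnergyMap", "fast_march", "march_from_voxel"]

_RECONVERGE_TOL = 1e-9


@dataclass
class EnergyMap:
    """Arrival energies from one source (inf where unreached)."""

    values: np.ndarray
    source_voxel: np.ndarray
    source_mm: np.ndarray


def _offsets26() -> np.ndarray:
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    return np.array(offs, dtype=np.int64)


def _surface_partners(offs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each offset, the offsets adjacent to it on the cube surface.

    Two offsets are partners when they share a cube face (a coordinate equal
    and of magnitude 1 in both) and differ by at most 1 per axis, so the
    segment between them stays on the surface of the neighbourhood cube.
    """
    n = len(offs)
    partners = [[] for _ in range(n)]
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            oa, ob = offs[a], offs[b]
            if np.max(np.abs(oa - ob)) != 1:
                continue
            if any(oa[d] == ob[d] and abs(oa[d]) == 1 for d in range(3)):
                partners[a].append(b)
    width = max(len(p) for p in partners)
    table = np.full((n, width), -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for a, lst in enumerate(partners):
        counts[a] = len(lst)
        table[a, : len(lst)] = lst
    return table, counts


_OFFS = _offsets26()
_PART, _PART_N = _surface_partners(_OFFS)


def _opposites(offs: np.ndarray) -> np.ndarray:
    opp = np.empty(len(offs), dtype=np.int64)
    for a in range(len(offs)):
        for t in range(len(offs)):
            if np.all(offs[t] == -offs[a]):
                opp[a] = t
                break
    return opp


_OPP = _opposites(_OFFS)


@njit(cache=True)
def _heap_push(hv, hi, size, val, idx):
    i = size
    hv[i] = val
    hi[i] = idx
    while i > 0:
        p = (i - 1) >> 1
        if hv[p] <= hv[i]:
            break
        hv[p], hv[i] = hv[i], hv[p]
        hi[p], hi[i] = hi[i], hi[p]
        i = p
    return size + 1


@njit(cache=True)
def _heap_pop(hv, hi, size):
    val = hv[0]
    idx = hi[0]
    size -= 1
    hv[0] = hv[size]
    hi[0] = hi[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < size and hv[l] < hv[m]:
            m = l
        if r < size and hv[r] < hv[m]:
            m = r
        if m == i:
            break
        hv[m], hv[i] = hv[i], hv[m]
        hi[m], hi[i] = hi[i], hi[m]
        i = m
    return val, idx, size


@njit(cache=True)
def _metric_quad(T, v0, v1, v2):
    # v^t M v for packed symmetric (xx, yy, zz, xy, xz, yz)
    return (
        T[0] * v0 * v0
        + T[1] * v1 * v1
        + T[2] * v2 * v2
        + 2.0 * (T[3] * v0 * v1 + T[4] * v0 * v2 + T[5] * v1 * v2)
    )


@njit(cache=True, fastmath=True)
def _march_kernel(
    speed, tf6, spacing, src, offs, opp, part, part_n, radius, value_cap, mask,
    cheap_thresh,
):
    nx, ny, nz = speed.shape
    nvox = nx * ny * nz
    u = np.full(nvox, 1e300)
    status = np.zeros(nvox, dtype=np.uint8)  # 0 far, 1 narrow, 2 accepted

    cap = 32 * 1024
    hv = np.empty(cap)
    hi = np.empty(cap, dtype=np.int64)
    size = 0

    # mm step vectors of the 26 offsets
    step = np.empty((26, 3))
    for a in range(26):
        for d in range(3):
            step[a, d] = offs[a, d] * spacing[d]

    s0 = src[0] * ny * nz + src[1] * nz + src[2]
    u[s0] = 0.0
    size = _heap_push(hv, hi, size, 0.0, s0)

    while size > 0:
        val, idx, size = _heap_pop(hv, hi, size)
        if status[idx] == 2 and val > u[idx] + _RECONVERGE_TOL:
            continue
        if val > u[idx]:
            continue
        if val > value_cap:
            break
        status[idx] = 2
        xi = idx // (ny * nz)
        yi = (idx // nz) % ny
        zi = idx % nz

        for a in range(26):
            px = xi + offs[a, 0]
            py = yi + offs[a, 1]
            pz = zi + offs[a, 2]
            if px < 0 or px >= nx or py < 0 or py >= ny or pz < 0 or pz >= nz:
                continue
            nidx = px * ny * nz + py * nz + pz
            if not mask[nidx]:
                continue
            dx = (px - src[0]) * spacing[0]
            dy = (py - src[1]) * spacing[1]
            dz = (pz - src[2]) * spacing[2]
            if dx * dx + dy * dy + dz * dz > radius * radius:
                continue

            sp = speed[px, py, pz]
            inv_s = 1.0 / sp
            T = tf6[nidx]
            # offset of the accepted voxel as seen from the neighbour
            b = opp[a]
            u1 = u[idx]
            h1x, h1y, h1z = step[b, 0], step[b, 1], step[b, 2]
            best = u1 + np.sqrt(_metric_quad(T, h1x, h1y, h1z)) * inv_s

            # two-point updates on surface edges through the accepted voxel;
            # skipped in the slow noise floor, where first-order accuracy
            # is irrelevant (geodesics never travel there)
            n_part = part_n[b] if sp >= cheap_thresh else 0
            for q in range(n_part):
                o2 = part[b, q]
                qx = px + offs[o2, 0]
                qy = py + offs[o2, 1]
                qz = pz + offs[o2, 2]
                if qx < 0 or qx >= nx or qy < 0 or qy >= ny or qz < 0 or qz >= nz:
                    continue
                qidx = qx * ny * nz + qy * nz + qz
                if status[qidx] != 2:
                    continue
                u2 = u[qidx]
                if u2 > 1e299:
                    continue
                h2x, h2y, h2z = step[o2, 0], step[o2, 1], step[o2, 2]
                ddx, ddy, ddz = h2x - h1x, h2y - h1y, h2z - h1z
                aa = _metric_quad(T, ddx, ddy, ddz)
                cc = _metric_quad(T, h1x, h1y, h1z)
                bb = 2.0 * (
                    T[0] * h1x * ddx
                    + T[1] * h1y * ddy
                    + T[2] * h1z * ddz
                    + T[3] * (h1x * ddy + h1y * ddx)
                    + T[4] * (h1x * ddz + h1z * ddx)
                    + T[5] * (h1y * ddz + h1z * ddy)
                )
                du = u2 - u1
                E = (sp * du) * (sp * du)
                A = 4.0 * aa * (aa - E)
                B = 4.0 * bb * (aa - E)
                C = bb * bb - 4.0 * E * cc
                if A != 0.0:
                    disc = B * B - 4.0 * A * C
                    if disc >= 0.0:
                        sq = np.sqrt(disc)
                        for sgn in (-1.0, 1.0):
                            t = (-B + sgn * sq) / (2.0 * A)
                            if 0.0 < t < 1.0:
                                qv = (aa * t + bb) * t + cc
                                if qv > 0.0:
                                    f = u1 + t * du + np.sqrt(qv) * inv_s
                                    if f < best:
                                        best = f
                elif B != 0.0:
                    t = -C / B
                    if 0.0 < t < 1.0:
                        qv = (aa * t + bb) * t + cc
                        if qv > 0.0:
                            f = u1 + t * du + np.sqrt(qv) * inv_s
                            if f < best:
                                best = f

            if best < u[nidx] - _RECONVERGE_TOL:
                u[nidx] = best
                if status[nidx] == 2:
                    status[nidx] = 1  # re-open improved accepted voxel
                if size >= cap:
                    newcap = cap * 2
                    nhv = np.empty(newcap)
                    nhi = np.empty(newcap, dtype=np.int64)
                    nhv[:size] = hv[:size]
                    nhi[:size] = hi[:size]
                    hv = nhv
                    hi = nhi
                    cap = newcap
                size = _heap_push(hv, hi, size, best, nidx)

    return u.reshape(nx, ny, nz)


@njit(cache=True)
def _finalize_unreached(u):
    out = u.copy()
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            for k in range(out.shape[2]):
                if out[i, j, k] > 1e299:
                    out[i, j, k] = np.inf
    return out


def march_from_voxel(
    cvm: np.ndarray,
    tf6: np.ndarray,
    spacing,
    source_voxel,
    radius: float = np.inf,
    value_cap: float = np.inf,
    domain_mask: np.ndarray | None = None,
    eps_floor_rel: float = 1e-6,
    cheap_rel: float = 0.0,
) -> np.ndarray:
    """Arrival-energy map from one source voxel (low-level entry point)."""
    cvm = np.ascontiguousarray(cvm, dtype=np.float64)
    cmax = float(cvm.max())
    if cmax <= 0:
        raise ValueError("vesselness potential is identically zero")
    src = np.asarray(source_voxel, dtype=np.int64)
    if np.any(src < 0) or np.any(src >= cvm.shape):
        raise ValueError("source outside the volume")
    speed = cvm + eps_floor_rel * cmax
    tfr = np.ascontiguousarray(
        tf6.reshape(-1, 6), dtype=np.float64
    )
    if domain_mask is None:
        mask = np.ones(cvm.size, dtype=np.bool_)
    else:
        mask = np.ascontiguousarray(domain_mask.reshape(-1), dtype=np.bool_)
        mask[src[0] * cvm.shape[1] * cvm.shape[2] + src[1] * cvm.shape[2] + src[2]] = True
    spc = np.asarray(spacing, dtype=np.float64)
    rad = np.float64(radius if np.isfinite(radius) else 1e30)
    cap = np.float64(value_cap if np.isfinite(value_cap) else 1e299)
    u = _march_kernel(speed, tfr, spc, src, _OFFS, _OPP, _PART, _PART_N, rad,
                      cap, mask, np.float64(cheap_rel) * speed.max())
    return _finalize_unreached(u)


def fast_march(potential, source_mm, radius: float = np.inf, **kwargs) -> EnergyMap:
    """Propagate a front from a world-coordinate source over the potential.

    The source is snapped to its nearest voxel; it must lie in a region of
    non-vanishing vesselness, otherwise the potential is unreachable.
    """
    src_vox = np.round(potential.world_to_voxel(source_mm)[0]).astype(int)
    src_vox = np.clip(src_vox, 0, np.array(potential.cvm.shape) - 1)
    if potential.cvm[tuple(src_vox)] <= 0:
        raise ValueError("source lies in a zero-vesselness region")
    # exponentiate the Log-Euclidean metric once per potential
    tf_eucl = kwargs.pop("tf_eucl6", None)
    if tf_eucl is None:
        tf_eucl = euclidean_tf6(potential)
    values = march_from_voxel(
        potential.cvm,
        tf_eucl,
        potential.spacing,
        src_vox,
        radius=radius,
        **kwargs,
    )
    return EnergyMap(
        values=values,
        source_voxel=src_vox,
        source_mm=np.asarray(source_mm, dtype=float),
    )


def euclidean_tf6(potential) -> np.ndarray:
    """Packed Euclidean tensors (xx, yy, zz, xy, xz, yz) of the potential."""
    return potential.tf6_euclidean()
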