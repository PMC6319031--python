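"""Per-scale synthesis of the scalar vesselness and tensor saliency maps.

At one pyramid scale the image is downsampled, scanned with the steered
tubular kernel over an icosphere to find candidate vessel voxels (seeds) and
their local orientations, and then densely filtered with the full curvilinear
dictionary steered along those orientations.  The products are the connected
vesselness map (CVM_s), boundary and background maps (BDM_s, BGM_s), and a
Log-Euclidean tensor field (TF_s) blended from the steered tensor patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy import ndimage
from skimage.transform import resize

from numba import njit

from .kernels import KernelDictionary, SLoGSKernel, steer_kernel
from .orientations import OrientationSet, icosphere_bases

__all__ = [
    "Volume",
    "ScaleMaps",
    "downsample",
    "tubular_saliency",
    "detect_seeds",
    "synthesize_scale",
]


@dataclass
class Volume:
    """A 3D scalar image with its voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]


@dataclass
class ScaleMaps:
    """Products of one pyramid scale, all on the downsampled grid."""

    scale: float
    affine: np.ndarray
    v_tube: np.ndarray
    seeds: np.ndarray            # (n, 3) voxel indices
    thetas: OrientationSet
    cvm_s: np.ndarray
    bdm_s: np.ndarray
    bgm_s: np.ndarray
    tf_s: np.ndarray             # (nx, ny, nz, 6) Log-Euclidean
    weight_map: np.ndarray


class _FFTConv:
    """Linear 'same' convolution of one image with many small kernels,
    with the padded image transform computed once."""

    def __init__(self, image: np.ndarray, support_radius: int):
        self.r = int(support_radius)
        self.n = image.shape
        self.fshape = tuple(sfft.next_fast_len(s + 2 * self.r) for s in self.n)
        self.img_f = sfft.rfftn(image.astype(np.float32), self.fshape)

    def kernel_fft(self, kernel: np.ndarray) -> np.ndarray:
        return sfft.rfftn(kernel.astype(np.float32), self.fshape)

    def conv(self, kernel: np.ndarray) -> np.ndarray:
        return self.finish(self.img_f * self.kernel_fft(kernel))

    def finish(self, freq: np.ndarray) -> np.ndarray:
        full = sfft.irfftn(freq, self.fshape)
        sl = tuple(slice(self.r, self.r + s) for s in self.n)
        return full[sl]


def _resize_affine(affine: np.ndarray, old_shape, new_shape) -> np.ndarray:
    """Affine for a grid resized with pixel-area (center) alignment."""
    r = np.asarray(old_shape, dtype=float) / np.asarray(new_shape, dtype=float)
    out = affine.copy()
    out[:3, :3] = affine[:3, :3] * r
    out[:3, 3] = affine[:3, 3] + affine[:3, :3] @ (0.5 * r - 0.5)
    return out


def downsample(volume: Volume, scale: float) -> Volume:
    """Antialiased downsampling that preserves world coordinates.

    Gaussian prefilter at sigma = 0.5/scale voxels, then resampling; the
    affine is rescaled so landmarks keep their world position.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if scale == 1:
        return volume
    new_shape = tuple(max(1, int(round(s * scale))) for s in volume.data.shape)
    blurred = ndimage.gaussian_filter(volume.data.astype(float), sigma=0.5 / scale)
    data = resize(blurred, new_shape, order=1, anti_aliasing=False,
                  preserve_range=True)
    return Volume(data, _resize_affine(volume.affine, volume.data.shape, new_shape))


def tubular_saliency(
    v_dwn: Volume, tubular: SLoGSKernel, omega_ico: OrientationSet
) -> np.ndarray:
    """Sum of positive-part tubular-kernel responses over icosphere bases."""
    r = tubular.support_radius
    if min(v_dwn.data.shape) < 2 * r + 1:
        raise ValueError("kernel support does not fit inside the volume")
    conv = _FFTConv(v_dwn.data, r)
    hann = _hann3(r)
    out = np.zeros(v_dwn.data.shape, dtype=np.float32)
    for basis in omega_ico.bases:
        K, _ = _steered_arrays(tubular, basis, hann)
        out += np.maximum(0.0, conv.conv(K))
    return out


def _hessian_field(vol: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-derivative Hessian, shape (nx, ny, nz, 3, 3)."""
    H = np.empty(vol.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            H[..., i, j] = H[..., j, i] = ndimage.gaussian_filter(
                vol, sigma=sigma, order=tuple(order)
            )
    return H


def detect_seeds(
    v_tube: np.ndarray,
    quantile_p: float = 75.0,
    hessian_sigma: float = 1.0,
    max_bases: int = 2000,
    orientation_level: int = 2,
):
    """Seed voxels and their orientation bases from the tubular saliency map.

    Seeds satisfy three conditions jointly: negative divergence of the
    gradient field (Laplacian sinks), all three Hessian eigenvalues negative
    (local ridge maxima), and saliency at or above the given percentile of
    the strictly positive samples.  Each seed's principal Hessian direction
    is snapped to the nearest icosphere direction of the given subdivision
    level; the returned steering set is the (deduplicated) set of snapped
    bases ordered by seed strength.  Snapping keeps the steering set small
    and lets steered kernels be reused across scales and volumes — the
    quantization error is below the icosphere's own angular spacing.
    """
    v = np.asarray(v_tube, dtype=float)
    if v.min() < 0:
        raise ValueError("tubular saliency must be non-negative")
    pos = v[v > 0]
    if pos.size == 0:
        import warnings

        warnings.warn("tubular saliency has no positive samples; no seeds")
        return np.empty((0, 3), dtype=int), OrientationSet([], "data-driven")

    lap = ndimage.gaussian_laplace(v, sigma=hessian_sigma)
    H = _hessian_field(v, hessian_sigma)
    eigvals = np.linalg.eigvalsh(H)
    thr = np.percentile(pos, quantile_p)
    mask = (lap < 0) & np.all(eigvals < 0, axis=-1) & (v >= thr)
    seeds = np.argwhere(mask)
    if seeds.shape[0] == 0:
        return seeds, OrientationSet([], "data-driven")

    order = np.argsort(-v[tuple(seeds.T)], kind="stable")
    seeds = seeds[order]

    lam, Q = np.linalg.eigh(H[tuple(seeds.T)])
    o = np.argsort(np.abs(lam), axis=-1, kind="stable")
    Q = np.take_along_axis(Q, o[:, None, :], axis=-1)
    principal = Q[:, :, 0]

    ico = icosphere_bases(orientation_level)
    dirs = ico.directions()
    snapped = np.argmax(np.abs(principal @ dirs.T), axis=1)
    bases, seen = [], set()
    for k in snapped:
        k = int(k)
        if k in seen:
            continue
        seen.add(k)
        bases.append(ico.bases[k])
        if len(bases) >= max_bases:
            break
    return seeds, OrientationSet(bases, "data-driven")


def _hann3(support_radius: int) -> np.ndarray:
    w = np.hanning(2 * support_radius + 3)[1:-1]  # non-zero at support ends
    return w[:, None, None] * w[None, :, None] * w[None, None, :]


# steered kernels are deterministic functions of (params, support, basis);
# the cache lets the fixed icosphere-quantized orientations reuse them
# across scales and volumes
_STEER_CACHE: dict = {}


def _steered_arrays(kern: SLoGSKernel, basis: np.ndarray, hann: np.ndarray):
    """(scalar kernel, blend patch) of a steered kernel, cached.

    The blend patch has 7 channels: the Hann-windowed impulse and its
    products with the 6 Log-Euclidean tensor components.
    """
    key = (
        kern.params.sigma,
        kern.params.c,
        kern.support_radius,
        np.round(basis, 10).tobytes(),
    )
    hit = _STEER_CACHE.get(key)
    if hit is not None:
        return hit
    sk = steer_kernel(kern, basis)
    wk = (sk.impulse * hann).astype(np.float32)
    patch = np.empty(wk.shape + (7,), dtype=np.float32)
    patch[..., 0] = wk
    six = sk.tensor_patch.six_components
    for c in range(6):
        patch[..., c + 1] = wk * six[..., c]
    out = (sk.kernel.astype(np.float32), patch)
    _STEER_CACHE[key] = out
    return out


@njit(cache=True)
def _scatter_blend(acc, vox, val, pair_idx, patches):
    """acc[ch] += val * patch(pair)[ch] around each significant voxel."""
    S = patches.shape[1]
    r = S // 2
    nx, ny, nz = acc.shape[1], acc.shape[2], acc.shape[3]
    for i in range(vox.shape[0]):
        x, y, z = vox[i, 0], vox[i, 1], vox[i, 2]
        p = pair_idx[i]
        v = val[i]
        for a in range(S):
            xa = x + a - r
            if xa < 0 or xa >= nx:
                continue
            for b in range(S):
                yb = y + b - r
                if yb < 0 or yb >= ny:
                    continue
                for c in range(S):
                    zc = z + c - r
                    if zc < 0 or zc >= nz:
                        continue
                    w = v
                    for ch in range(7):
                        acc[ch, xa, yb, zc] += w * patches[p, a, b, c, ch]


def synthesize_scale(
    v_dwn: Volume,
    dictionary: KernelDictionary,
    thetas: OrientationSet,
    scale: float = 1.0,
    v_tube: np.ndarray | None = None,
    seeds: np.ndarray | None = None,
    weight_floor: float = 1e-6,
    log_clip: float = 3.0,
    blend_rel: float = 1e-3,
    blend_max_voxels: int = 32768,
) -> ScaleMaps:
    """Densely filter one scale with the steered dictionary.

    CVM_s sums the positive-part responses of every dictionary kernel steered
    along every orientation.  The tensor field is the weight-normalized
    Log-Euclidean blend of the steered tensor patch of the kernel with the
    maximal filter response at each voxel, scattered over the patch
    neighbourhood with weight (response x steered impulse x Hann window);
    it is renormalized to unit determinant, and voxels with no support
    receive the isotropic identity.  BDM_s / BGM_s are the degenerate-kernel
    responses on the image negative.
    """
    if len(thetas) == 0:
        raise ValueError("need at least one steering orientation")
    img = v_dwn.data.astype(np.float32)
    r = dictionary.curvilinear[0].support_radius
    conv = _FFTConv(img, r)
    # image negative: bright background, dark vessels
    neg_f = sfft.rfftn((img.max() - img), conv.fshape)

    hann = _hann3(r)
    cvm = np.zeros(img.shape, dtype=np.float32)
    # per-voxel top-3 responding (kernel, orientation) pairs: blending more
    # than one orientation keeps bifurcation voxels near-isotropic, which
    # the geodesic stage needs to turn corners without cost penalties
    top_val = np.zeros((3,) + img.shape, dtype=np.float32)
    top_idx = np.zeros((3,) + img.shape, dtype=np.uint16)

    patches = []
    pair = 0
    for basis in thetas.bases:
        for kern in dictionary.curvilinear:
            K, patch = _steered_arrays(kern, basis, hann)
            patches.append(patch)
            resp = np.maximum(0.0, conv.conv(K)).astype(np.float32)
            cvm += resp
            for rank in range(3):
                better = resp > top_val[rank]
                if not better.any():
                    break
                for lower in range(2, rank, -1):
                    top_val[lower][better] = top_val[lower - 1][better]
                    top_idx[lower][better] = top_idx[lower - 1][better]
                top_val[rank][better] = resp[better]
                top_idx[rank][better] = pair
                resp = np.where(better, 0.0, resp)  # remaining ranks
            pair += 1
    patch_stack = np.stack(patches)

    # scatter the winning patches at the significant voxels
    thr = blend_rel * float(top_val[0].max())
    sig = np.argwhere(top_val[0] > thr)
    if len(sig) > blend_max_voxels:
        vals = top_val[0][tuple(sig.T)]
        keep = np.argpartition(-vals, blend_max_voxels)[:blend_max_voxels]
        sig = sig[keep]
    acc = np.zeros((7,) + img.shape, dtype=np.float32)
    if len(sig):
        sigc = np.ascontiguousarray(sig)
        for rank in range(3):
            vals = top_val[rank][tuple(sig.T)]
            nz = vals > 0
            if not nz.any():
                continue
            _scatter_blend(
                acc,
                np.ascontiguousarray(sigc[nz]),
                np.ascontiguousarray(vals[nz]),
                np.ascontiguousarray(top_idx[rank][tuple(sig.T)][nz].astype(np.int64)),
                patch_stack,
            )

    bdm = conv.finish(neg_f * conv.kernel_fft(dictionary.delta_log))
    bgm = np.maximum(0.0, conv.finish(neg_f * conv.kernel_fft(dictionary.nu_log)))

    W = acc[0]
    np.clip(W, 0.0, None, out=W)
    valid = W > weight_floor * max(W.max(), 1e-30)
    tf = np.zeros(img.shape + (6,), dtype=np.float32)
    for c in range(6):
        tf[..., c] = np.where(valid, acc[c + 1] / np.where(valid, W, 1.0), 0.0)
    # the blend is a convex combination of patch logs, whose range the
    # clip preserves; it only guards against low-weight division artifacts
    np.clip(tf, -log_clip, log_clip, out=tf)
    # unit determinant: remove the trace of the log tensor
    trace = (tf[..., 0] + tf[..., 1] + tf[..., 2]) / 3.0
    for c in range(3):
        tf[..., c] -= trace

    return ScaleMaps(
        scale=scale,
        affine=v_dwn.affine,
        v_tube=v_tube if v_tube is not None else np.zeros_like(cvm),
        seeds=seeds if seeds is not None else np.empty((0, 3), dtype=int),
        thetas=thetas,
        cvm_s=cvm,
        bdm_s=bdm,
        bgm_s=bgm,
        tf_s=tf,
        weight_map=W,
    )
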