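"""Steerable curvilinear Laplacian-of-Gaussian kernels and their tensor patches.

The filterbank element is a trivariate Gaussian impulse whose support is
warped by shear / bend / tilt coefficients, differentiated twice along its
own gradient (gauge) direction.  Each kernel carries a companion field of
unit-determinant symmetric positive-definite tensors, stored in the
Log-Euclidean domain, that encodes the local orientation and anisotropy of
the template vessel segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianSwirlParams",
    "TensorPatch",
    "SLoGSKernel",
    "KernelDictionary",
    "eval_gamma",
    "build_slogs_kernel",
    "build_tensor_patch",
    "build_degenerate_kernels",
    "steer_kernel",
    "default_dictionary",
]

# threshold (relative to the max gradient norm) below which the gauge
# direction is treated as degenerate and the 1/3 limit convention applies
_GRAD_EPS_REL = 1e-12

# canonical-frame orientation bases, keyed by (sigma, c, support_radius)
_PHI_CACHE: dict = {}


@dataclass(frozen=True)
class GaussianSwirlParams:
    """Scales and curvature coefficients of a curvilinear Gaussian impulse.

    Parameters
    ----------
    sigma : tuple of float
        Spatial scales (voxels) along the elongation axis and the two
        cross-sectional axes; all strictly positive.
    c : tuple of float
        Curvature coefficients ``(c0, c1, c2)``: in-plane shear, quadratic
        bend, and cubic tilt of the support (dimensionless).
    """

    sigma: tuple[float, float, float]
    c: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma, dtype=float)
        if sig.shape != (3,) or not np.all(np.isfinite(sig)) or np.any(sig <= 0):
            raise ValueError(f"sigma must be 3 positive finite values, got {self.sigma}")
        cc = np.asarray(self.c, dtype=float)
        if cc.shape != (3,) or not np.all(np.isfinite(cc)):
            raise ValueError(f"c must be 3 finite values, got {self.c}")


@dataclass
class TensorPatch:
    """6-channel Log-Euclidean field of unit-determinant SPD tensors.

    Channel order is ``(xx, yy, zz, xy, xz, yz)`` of the matrix logarithm.
    """

    six_components: np.ndarray  # (nx, ny, nz, 6)

    def euclidean(self) -> np.ndarray:
        """Exponentiate back to Euclidean tensors, shape (nx, ny, nz, 3, 3)."""
        return expm_field(self.six_components)


@dataclass
class SLoGSKernel:
    """A discrete steerable curvilinear kernel with its companions.

    Attributes
    ----------
    impulse : ndarray
        The generating Gaussian impulse on the cubic support.
    kernel : ndarray
        Second directional derivative of the impulse along its gauge
        (normalized gradient) direction, via the Hessian eigen-factorization.
    tensor_patch : TensorPatch or None
        Unit-determinant tensor companion (None for degenerate kernels).
    orientation_basis : ndarray
        3x3 rotation: the impulse-weighted integral of the per-voxel
        Hessian eigenbases, projected to the nearest rotation.
    params : GaussianSwirlParams
    diagnostics : dict
        Counts of voxels where fallback conventions were applied.
    """

    impulse: np.ndarray
    kernel: np.ndarray
    tensor_patch: TensorPatch | None
    orientation_basis: np.ndarray
    params: GaussianSwirlParams
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    support_radius: int = 5
    diagnostics: dict = field(default_factory=dict)


@dataclass
class KernelDictionary:
    """The filtering dictionary: curvilinear kernels plus the degenerate pair.

    ``delta_log`` and ``nu_log`` are scalar-only (no tensor companion): the
    pseudo-impulsive edge detector and the wide flat kernel sensitive to
    homogeneous regions.
    """

    curvilinear: list[SLoGSKernel]
    tubular: SLoGSKernel
    delta_log: np.ndarray
    nu_log: np.ndarray


# ---------------------------------------------------------------------------
# analytic impulse, gradient and Hessian

def _warp(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Warped coordinates of the curvilinear support; x is (..., 3)."""
    x1, x2, x3 = x[..., 0], x[..., 1], x[..., 2]
    return np.stack(
        [x1, x2 + c[0] * x1 + c[1] * x1**2, x3 + c[2] * x1**3], axis=-1
    )


def eval_gamma(x, params: GaussianSwirlParams) -> np.ndarray:
    """Evaluate the curvilinear trivariate Gaussian impulse at point(s) x."""
    x = np.asarray(x, dtype=float)
    sig = np.asarray(params.sigma, dtype=float)
    X = _warp(x, np.asarray(params.c, dtype=float))
    norm = np.prod(1.0 / np.sqrt(2.0 * np.pi * sig**2))
    return norm * np.exp(-0.5 * np.sum((X / sig) ** 2, axis=-1))


def _gamma_grad_hess(x: np.ndarray, params: GaussianSwirlParams):
    """Analytic value, gradient and Hessian of the impulse at points x (...,3)."""
    sig = np.asarray(params.sigma, dtype=float)
    c = np.asarray(params.c, dtype=float)
    x1 = x[..., 0]
    X = _warp(x, c)
    g = eval_gamma(x, params)

    # Jacobian of the warp, J[d, j] = dX_d/dx_j
    J = np.zeros(x.shape[:-1] + (3, 3))
    J[..., 0, 0] = 1.0
    J[..., 1, 0] = c[0] + 2.0 * c[1] * x1
    J[..., 1, 1] = 1.0
    J[..., 2, 0] = 3.0 * c[2] * x1**2
    J[..., 2, 2] = 1.0

    u = -X / sig**2  # dlog(g)/dX_d
    grad = g[..., None] * np.einsum("...d,...dj->...j", u, J)

    # Hessian: J^T (u u^T - diag(1/sig^2)) J * g  + warp-curvature term on (1,1)
    M = np.einsum("...d,...e->...de", u, u)
    idx = np.arange(3)
    M[..., idx, idx] -= 1.0 / sig**2
    H = g[..., None, None] * np.einsum("...dj,...de,...ek->...jk", J, M, J)
    curv = g * (u[..., 1] * 2.0 * c[1] + u[..., 2] * 6.0 * c[2] * x1)
    H[..., 0, 0] += curv
    return g, grad, H


def _neglog_gamma_hess(x: np.ndarray, params: GaussianSwirlParams) -> np.ndarray:
    """Hessian of -log(impulse): J^T diag(1/sig^2) J plus warp curvature."""
    sig = np.asarray(params.sigma, dtype=float)
    c = np.asarray(params.c, dtype=float)
    x1 = x[..., 0]
    X = _warp(x, c)
    J = np.zeros(x.shape[:-1] + (3, 3))
    J[..., 0, 0] = 1.0
    J[..., 1, 0] = c[0] + 2.0 * c[1] * x1
    J[..., 1, 1] = 1.0
    J[..., 2, 0] = 3.0 * c[2] * x1**2
    J[..., 2, 2] = 1.0
    D = 1.0 / sig**2
    H = np.einsum("...dj,d,...dk->...jk", J, D, J)
    H[..., 0, 0] += X[..., 1] * D[1] * 2.0 * c[1] + X[..., 2] * D[2] * 6.0 * c[2] * x1
    return H


def _support_grid(support_radius: int) -> np.ndarray:
    r = int(support_radius)
    ax = np.arange(-r, r + 1, dtype=float)
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)


def _sorted_eigh(H: np.ndarray):
    """Eigendecomposition with |eigenvalue|-ascending order and fixed signs.

    Signs are fixed so that each eigenvector's largest-magnitude component is
    positive, making the basis deterministic.
    """
    lam, Q = np.linalg.eigh(H)
    order = np.argsort(np.abs(lam), axis=-1, kind="stable")
    lam = np.take_along_axis(lam, order, axis=-1)
    Q = np.take_along_axis(Q, order[..., None, :], axis=-1)
    # sign fix per eigenvector (columns of Q)
    comp = np.argmax(np.abs(Q), axis=-2)
    sgn = np.sign(np.take_along_axis(Q, comp[..., None, :], axis=-2))
    sgn[sgn == 0] = 1.0
    Q = Q * sgn
    return lam, Q


def _nearest_rotation(A: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix to the nearest rotation (polar SVD, det +1)."""
    U, _, Vt = np.linalg.svd(A)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def build_slogs_kernel(
    params: GaussianSwirlParams,
    support_radius: int = 5,
    rotation: np.ndarray | None = None,
) -> SLoGSKernel:
    """Build the scalar kernel, tensor patch and intrinsic basis of a swirl.

    The scalar kernel is the gauge second derivative ``w^t H(G) w`` evaluated
    through the eigen-factorization with modulation coefficients
    ``gamma_l = (grad.q_l)^2 / |grad|^2`` (the 1/3 limit where the gradient
    vanishes).  ``rotation`` evaluates the analytic fields on a rotated grid
    (the steering path): the gauge derivative is rotation invariant, so the
    scalar kernel is simply sampled at the back-rotated coordinates, while
    tensors are conjugated.

    The truncated discrete kernel retains a small DC residue from the cut
    LoG tails; it is removed so the filterbank has zero response to constant
    images.
    """
    if support_radius < 2:
        raise ValueError("support_radius must be >= 2")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    x = _support_grid(support_radius) @ R  # local coords R^T x
    g, grad, H = _gamma_grad_hess(x, params)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite Hessian on kernel support")

    lam, Q = _sorted_eigh(H)
    gn2 = np.sum(grad**2, axis=-1)
    max_gn = float(np.sqrt(gn2.max()))
    degenerate = np.sqrt(gn2) < _GRAD_EPS_REL * max_gn

    proj = np.einsum("...j,...jl->...l", grad, Q)  # grad . q_l
    with np.errstate(divide="ignore", invalid="ignore"):
        gam = proj**2 / gn2[..., None]
    gam[degenerate] = 1.0 / 3.0
    K = np.sum(gam * lam, axis=-1)
    K = K - K.mean()

    # impulse-weighted integral of the eigenbases, projected to a rotation.
    # Evaluated in the canonical (unrotated) frame so the basis is intrinsic
    # to the kernel shape, then conjugated into the steered frame.
    if rotation is None:
        Phi = _nearest_rotation(np.einsum("abc,abcjl->jl", g, Q))
    else:
        key = (params.sigma, params.c, support_radius)
        Phi0 = _PHI_CACHE.get(key)
        if Phi0 is None:
            x0 = _support_grid(support_radius)
            g0, _, H0 = _gamma_grad_hess(x0, params)
            _, Q0 = _sorted_eigh(H0)
            Phi0 = _nearest_rotation(np.einsum("abc,abcjl->jl", g0, Q0))
            _PHI_CACHE[key] = Phi0
        Phi = R @ Phi0

    patch = build_tensor_patch(params, support_radius, rotation=R)
    return SLoGSKernel(
        impulse=g,
        kernel=K,
        tensor_patch=patch,
        orientation_basis=Phi,
        params=params,
        rotation=R,
        support_radius=support_radius,
        diagnostics={"degenerate_gradient_voxels": int(degenerate.sum())},
    )


def build_tensor_patch(
    params: GaussianSwirlParams,
    support_radius: int = 5,
    eig_floor: float = 1e-2,
    rotation: np.ndarray | None = None,
) -> TensorPatch:
    """Unit-determinant tensor field from the convexity of -log(impulse).

    Eigenvalues of ``H(-log G)`` are replaced by the canonical ellipsoid
    semiaxes ``psi_1 = l1/sqrt(l2 l3), psi_2 = l2/l3, psi_3 = 1`` (with
    ``|l1| <= |l2| <= |l3|``), normalized to unit determinant; stored as the
    6 independent Log-Euclidean components.
    """
    if support_radius < 2:
        raise ValueError("support_radius must be >= 2")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    x = _support_grid(support_radius) @ R
    Ht = _neglog_gamma_hess(x, params)
    lam, Q = _sorted_eigh(Ht)
    # -log(impulse) can lose convexity for strong warps near the support
    # boundary; a relative floor keeps the tensors SPD with bounded anisotropy
    floor = eig_floor * np.abs(lam).max(axis=-1, keepdims=True)
    lam = np.maximum(lam, floor)

    psi = np.empty_like(lam)
    psi[..., 0] = lam[..., 0] / np.sqrt(lam[..., 1] * lam[..., 2])
    psi[..., 1] = lam[..., 1] / lam[..., 2]
    psi[..., 2] = 1.0
    psi /= np.prod(psi, axis=-1, keepdims=True) ** (1.0 / 3.0)

    log_psi = np.log(psi)
    L = np.einsum("...jl,...l,...kl->...jk", Q, log_psi, Q)
    L = np.einsum("ab,...bc,dc->...ad", R, L, R)
    return TensorPatch(six_components=_sym_to6(L))


def _sym_to6(M: np.ndarray) -> np.ndarray:
    """Pack symmetric (..., 3, 3) into (..., 6): xx, yy, zz, xy, xz, yz."""
    return np.stack(
        [M[..., 0, 0], M[..., 1, 1], M[..., 2, 2],
         M[..., 0, 1], M[..., 0, 2], M[..., 1, 2]], axis=-1
    )


def _six_to_sym(v: np.ndarray) -> np.ndarray:
    M = np.empty(v.shape[:-1] + (3, 3), dtype=v.dtype)
    M[..., 0, 0] = v[..., 0]
    M[..., 1, 1] = v[..., 1]
    M[..., 2, 2] = v[..., 2]
    M[..., 0, 1] = M[..., 1, 0] = v[..., 3]
    M[..., 0, 2] = M[..., 2, 0] = v[..., 4]
    M[..., 1, 2] = M[..., 2, 1] = v[..., 5]
    return M


def expm_field(six: np.ndarray) -> np.ndarray:
    """Matrix exponential of a 6-channel symmetric log field -> (..., 3, 3)."""
    L = _six_to_sym(np.asarray(six, dtype=float))
    lam, Q = np.linalg.eigh(L)
    return np.einsum("...jl,...l,...kl->...jk", Q, np.exp(lam), Q)


def logm_field(T: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD (..., 3, 3) field -> 6 channels."""
    lam, Q = np.linalg.eigh(T)
    if np.any(lam <= 0):
        raise ValueError("tensor field is not positive definite")
    L = np.einsum("...jl,...l,...kl->...jk", Q, np.log(lam), Q)
    return _sym_to6(L)


def _analytic_log(x: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic 3D Laplacian of Gaussian at points x (..., 3)."""
    r2 = np.sum(x**2, axis=-1)
    g = (2.0 * np.pi * sigma**2) ** (-1.5) * np.exp(-r2 / (2.0 * sigma**2))
    return g * (r2 / sigma**4 - 3.0 / sigma**2)


def build_degenerate_kernels(
    support_radius: int = 5, sigma_delta: float = 0.8, sigma_nu: float = 8.0
):
    """The scalar-only degenerate pair: pseudo-impulsive and uniformly flat.

    ``delta_log`` (small sigma) is the analytic Laplacian of Gaussian, which
    fires on sharp intensity transitions; ``nu_log`` is the flat sigma->inf
    limit on the fixed support — a near-uniform positive averaging kernel
    (unit sum) that fires on homogeneous regions.  Neither carries a tensor
    companion.
    """
    if sigma_delta <= 0 or sigma_nu <= 0:
        raise ValueError("degenerate kernel sigmas must be positive")
    x = _support_grid(support_radius)
    nu = np.exp(-np.sum(x**2, axis=-1) / (2.0 * sigma_nu**2))
    nu /= nu.sum()
    return _analytic_log(x, sigma_delta), nu


def steer_kernel(kernel: SLoGSKernel, target_basis: np.ndarray) -> SLoGSKernel:
    """Rotate a kernel so its intrinsic basis maps onto ``target_basis``.

    Steering re-evaluates the analytic impulse, gauge-derivative kernel and
    tensor field on the back-rotated support grid (the rotation that maps
    the kernel's intrinsic basis onto the target), so repeated steering
    accumulates a single rotation and is exactly reversible.  Tensors are
    conjugated congruently (``R T R^t``), which preserves SPD and the unit
    determinant.  An identity rotation returns the kernel unchanged.
    """
    B = np.asarray(target_basis, dtype=float)
    if B.shape != (3, 3) or not np.allclose(B @ B.T, np.eye(3), atol=1e-8):
        raise ValueError("target basis must be a 3x3 orthonormal matrix")
    if np.linalg.det(B) < 0:
        raise ValueError("target basis must have determinant +1")
    R_delta = B @ kernel.orientation_basis.T
    if np.allclose(R_delta, np.eye(3), atol=1e-12):
        return kernel
    return build_slogs_kernel(
        kernel.params,
        support_radius=kernel.support_radius,
        rotation=R_delta @ kernel.rotation,
    )


DEFAULT_DICTIONARY_SPEC = [
    # (sigma, c): straight, two bends, two shears, two tilts
    ((2.0, 0.7, 0.7), (0.0, 0.0, 0.0)),
    ((2.0, 0.7, 0.7), (0.0, 0.1, 0.0)),
    ((2.0, 0.7, 0.7), (0.0, -0.1, 0.0)),
    ((2.0, 0.7, 0.7), (0.3, 0.0, 0.0)),
    ((2.0, 0.7, 0.7), (-0.3, 0.0, 0.0)),
    ((2.0, 0.7, 0.7), (0.0, 0.0, 0.02)),
    ((2.0, 0.7, 0.7), (0.0, 0.0, -0.02)),
]


def default_dictionary(
    support_radius: int = 5,
    entries=None,
    sigma_delta: float = 0.8,
    sigma_nu: float = 8.0,
) -> KernelDictionary:
    """Build the default dictionary: 7 curvilinear swirls, a tubular kernel,
    and the degenerate pair."""
    entries = entries if entries is not None else DEFAULT_DICTIONARY_SPEC
    curvi = [
        build_slogs_kernel(GaussianSwirlParams(tuple(s), tuple(c)), support_radius)
        for s, c in entries
    ]
    tubular = build_slogs_kernel(
        GaussianSwirlParams((2.0, 0.7, 0.7), (0.0, 0.0, 0.0)), support_radius
    )
    dlog, nlog = build_degenerate_kernels(support_radius, sigma_delta, sigma_nu)
    return KernelDictionary(
        curvilinear=curvi, tubular=tubular, delta_log=dlog, nu_log=nlog
    )
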