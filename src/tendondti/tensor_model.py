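"""Per-voxel diffusion tensor estimation and scalar maps.

The diffusion-weighted signal model is ``S(b, g) = S0 · exp(−b gᵀ D g)``
with D a symmetric 3×3 tensor (mm²/s).  Two fit routes are provided:

* :func:`fit_tensor_loglinear` — weighted least squares on the logged
  model (weights = squared predicted signal, predicted from an initial
  ordinary least-squares pass).  Exact on noise-free data; used as the
  initializer for the nonlinear fit.
* :func:`fit_tensor_nonlinear` — damped Gauss–Newton (Levenberg–Marquardt)
  on the un-logged model, batched over voxels.  Only objective-decreasing
  steps are accepted, so the final residual never exceeds the
  initializer's.  An optional positivity mode re-parameterizes D through
  its Cholesky factor, forcing non-negative eigenvalues.

Scalar maps follow the standard definitions: eigenvalues sorted
descending (λ1 axial, λ2/λ3 radial), MD their mean, and
``FA = sqrt(3/2) · sqrt(Σ(λᵢ−MD)²) / sqrt(Σλᵢ²)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import DWIProtocol, DWIVolume

__all__ = [
    "TensorField",
    "ScalarMaps",
    "fit_tensor_loglinear",
    "fit_tensor_nonlinear",
    "scalar_maps",
    "tensors_from_eigen",
    "pack_tensors",
    "unpack_tensors",
]

# packed component order used throughout
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")
_II = np.array([0, 1, 2, 0, 0, 1])
_JJ = np.array([0, 1, 2, 1, 2, 2])


def pack_tensors(matrices: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices → (..., 6) packed components."""
    m = np.asarray(matrices, dtype=float)
    return m[..., _II, _JJ]


def unpack_tensors(packed: np.ndarray) -> np.ndarray:
    """(..., 6) packed components → (..., 3, 3) symmetric matrices."""
    d = np.asarray(packed, dtype=float)
    out = np.zeros(d.shape[:-1] + (3, 3), dtype=float)
    out[..., _II, _JJ] = d
    out[..., _JJ, _II] = d
    return out


@dataclass
class TensorField:
    """Per-voxel symmetric tensors (packed 6-vector) plus fitted S0.

    ``valid`` flags voxels whose fit succeeded; downstream statistics use
    valid voxels only.  ``clamped`` marks voxels whose signals had to be
    clamped to a positive floor before taking logarithms.
    """

    tensors: np.ndarray                   # (X, Y, Z, 6) mm²/s
    s0: np.ndarray                        # (X, Y, Z)
    mask: np.ndarray                      # (X, Y, Z) bool, fit domain
    valid: np.ndarray                     # (X, Y, Z) bool
    voxel_dims: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    clamped: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def matrices(self) -> np.ndarray:
        return unpack_tensors(self.tensors)


@dataclass
class ScalarMaps:
    """Eigenvalue-derived scalar maps; NaN outside the valid fit domain."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    md: np.ndarray
    fa: np.ndarray
    valid: np.ndarray
    voxel_dims: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"lambda1": self.lambda1, "lambda2": self.lambda2,
                "lambda3": self.lambda3, "md": self.md, "fa": self.fa}


def _resolve(dwi, protocol, mask):
    if isinstance(dwi, DWIVolume):
        data = dwi.data
        protocol = protocol or dwi.protocol
        dims, origin = dwi.voxel_dims, dwi.origin
    else:
        data = np.asarray(dwi, dtype=float)
        dims, origin = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
    if protocol is None:
        raise ValueError("a DWIProtocol is required")
    if data.ndim != 4 or data.shape[3] != len(protocol):
        raise ValueError("protocol/tensor grid mismatch: DWI volume count "
                         f"{data.shape[3:]} does not match protocol length "
                         f"{len(protocol)}")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match the DWI grid")
    return data, protocol, mask, dims, origin


def _check_design(protocol: DWIProtocol) -> np.ndarray:
    A = protocol.design_matrix()
    if len(protocol) < 7:
        raise ValueError("tensor fitting needs at least 7 volumes")
    if protocol.n_b0 < 1:
        raise ValueError("tensor fitting needs at least one b = 0 volume")
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError(
            "rank-deficient gradient design: the encoding directions do not "
            "span all six tensor components (e.g. coplanar directions)"
        )
    return A


def fit_tensor_loglinear(dwi, protocol: DWIProtocol | None = None,
                         mask: np.ndarray | None = None) -> TensorField:
    """Weighted log-linear tensor fit.

    Solves ``ln S = ln S0 − b gᵀDg`` per voxel: an ordinary least-squares
    pass supplies predicted signals, whose squares weight the second
    (definitive) pass.  Non-positive signals are clamped to a small
    positive floor and the voxel is flagged in ``clamped``.
    """
    data, protocol, mask, dims, origin = _resolve(dwi, protocol, mask)
    A = _check_design(protocol)
    S = data[mask]                                     # (N, n)
    if S.size == 0:
        raise ValueError("empty mask: nothing to fit")

    positive = S > 0
    floor = 1e-8 * (np.median(S[positive]) if positive.any() else 1.0)
    clamped_vox = ~positive.all(axis=1)
    S = np.where(positive, S, floor)
    y = np.log(S)

    pinv = np.linalg.pinv(A)
    x = y @ pinv.T                                     # OLS, (N, 7)
    pred = x @ A.T
    w = np.exp(2.0 * np.clip(pred, -300, 300))         # squared predicted signal
    Aw = A[None, :, :] * w[:, :, None]                 # (N, n, 7)
    H = np.einsum("vni,nj->vij", Aw, A)
    g = np.einsum("vni,vn->vi", Aw, y)
    try:
        x = np.linalg.solve(H, g[..., None])[..., 0]
    except np.linalg.LinAlgError:
        x = np.einsum("vij,vj->vi", np.linalg.pinv(H), g)

    finite = np.isfinite(x).all(axis=1)
    shape = data.shape[:3]
    tensors = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    clamped = np.zeros(shape, dtype=bool)
    tensors[mask] = np.where(finite[:, None], x[:, 1:], 0.0)
    s0[mask] = np.where(finite, np.exp(np.clip(x[:, 0], -300, 300)), 0.0)
    valid[mask] = finite
    clamped[mask] = clamped_vox
    return TensorField(tensors, s0, mask, valid, dims, origin, clamped,
                       meta={"method": "loglinear"})


# ---------------------------------------------------------------------------
# nonlinear (batched Levenberg–Marquardt)
# ---------------------------------------------------------------------------

def _chol_pack(L6: np.ndarray) -> np.ndarray:
    """Cholesky params (l11, l22, l33, l21, l31, l32) → packed D = LLᵀ."""
    l11, l22, l33, l21, l31, l32 = (L6[..., k] for k in range(6))
    return np.stack([
        l11 * l11,
        l21 * l21 + l22 * l22,
        l31 * l31 + l32 * l32 + l33 * l33,
        l11 * l21,
        l11 * l31,
        l21 * l31 + l22 * l32,
    ], axis=-1)


def _chol_jacobian(L6: np.ndarray) -> np.ndarray:
    """(N, 6, 6) ∂d/∂l with d rows (xx,yy,zz,xy,xz,yz), l cols as above."""
    N = L6.shape[0]
    l11, l22, l33, l21, l31, l32 = (L6[:, k] for k in range(6))
    J = np.zeros((N, 6, 6))
    J[:, 0, 0] = 2 * l11
    J[:, 1, 3] = 2 * l21
    J[:, 1, 1] = 2 * l22
    J[:, 2, 4] = 2 * l31
    J[:, 2, 5] = 2 * l32
    J[:, 2, 2] = 2 * l33
    J[:, 3, 0] = l21
    J[:, 3, 3] = l11
    J[:, 4, 0] = l31
    J[:, 4, 4] = l11
    J[:, 5, 3] = l31
    J[:, 5, 4] = l21
    J[:, 5, 1] = l32
    J[:, 5, 5] = l22
    return J


def _chol_init(d6: np.ndarray, s0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-PSD Cholesky factors and log-S0 from an unconstrained init."""
    D = unpack_tensors(d6)
    w, V = np.linalg.eigh(D)
    floor = 1e-6 * np.maximum(np.abs(w).max(axis=-1, keepdims=True), 1e-12)
    w = np.maximum(w, floor)
    Dpsd = np.einsum("...ik,...k,...jk->...ij", V, w, V)
    L = np.linalg.cholesky(Dpsd)
    L6 = np.stack([L[..., 0, 0], L[..., 1, 1], L[..., 2, 2],
                   L[..., 1, 0], L[..., 2, 0], L[..., 2, 1]], axis=-1)
    ls0 = np.log(np.maximum(s0, 1e-12))
    return L6, ls0


def fit_tensor_nonlinear(dwi, protocol: DWIProtocol | None = None,
                         mask: np.ndarray | None = None,
                         init: TensorField | None = None,
                         positivity: bool = False,
                         max_iter: int = 100,
                         rtol: float = 1e-10) -> TensorField:
    """Nonlinear least squares on ``S0 · exp(−b gᵀDg)``, batched over voxels.

    A damped Gauss–Newton (Levenberg–Marquardt) iteration starts from the
    log-linear fit (or ``init``).  Steps are accepted only when they lower
    the per-voxel residual sum of squares, so the objective never exceeds
    the initializer's.  Iteration stops when the relative objective
    decrease falls below ``rtol`` or after ``max_iter`` sweeps; voxels that
    never converge are flagged invalid rather than raising.

    With ``positivity=True`` the tensor is parameterized as D = LLᵀ through
    its Cholesky factor (and S0 through its logarithm), so all eigenvalues
    of the fitted tensor are non-negative by construction.
    """
    data, protocol, mask, dims, origin = _resolve(dwi, protocol, mask)
    _check_design(protocol)
    if init is None:
        init = fit_tensor_loglinear(
            DWIVolume(data, protocol, dims, origin), mask=mask)

    q = protocol.quad_design()                         # (n, 6)
    Y = data[mask]                                     # (N, n)
    d0 = init.tensors[mask]
    s00 = np.maximum(init.s0[mask], 1e-12)
    N = Y.shape[0]

    if positivity:
        L6, ls0 = _chol_init(d0, s00)
        theta = np.concatenate([ls0[:, None], L6], axis=1)
    else:
        theta = np.concatenate([s00[:, None], d0], axis=1)

    def unpack_theta(th):
        if positivity:
            s0 = np.exp(np.clip(th[:, 0], -300, 300))
            d = _chol_pack(th[:, 1:])
        else:
            s0 = th[:, 0]
            d = th[:, 1:]
        return s0, d

    def objective(th):
        s0, d = unpack_theta(th)
        pred = s0[:, None] * np.exp(-np.clip(d @ q.T, -300, 300))
        r = pred - Y
        return np.einsum("vn,vn->v", r, r), pred, r

    obj, pred, resid = objective(theta)
    lam = np.full(N, 1e-3)
    active = np.ones(N, dtype=bool)
    converged = np.zeros(N, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        th_a = theta[idx]
        pred_a = pred[idx]
        r_a = resid[idx]
        if positivity:
            # J wrt (log s0, L6): chain rule through d = LLᵀ
            Jd = -pred_a[:, :, None] * q[None, :, :]           # (Na, n, 6)
            dd_dl = _chol_jacobian(th_a[:, 1:])                # (Na, 6, 6)
            J = np.concatenate(
                [pred_a[:, :, None], np.einsum("vnk,vkl->vnl", Jd, dd_dl)],
                axis=2)
        else:
            s0_a = th_a[:, 0]
            E = pred_a / np.where(s0_a[:, None] == 0, 1.0, s0_a[:, None])
            J = np.concatenate(
                [E[:, :, None], -pred_a[:, :, None] * q[None, :, :]], axis=2)

        H = np.einsum("vni,vnj->vij", J, J)
        grad = np.einsum("vni,vn->vi", J, r_a)
        diag = np.einsum("vii->vi", H)
        diag = np.maximum(diag, 1e-30)
        # lam scales the diagonal (Marquardt form)
        Hd = H.copy()
        Hd[:, np.arange(7), np.arange(7)] += lam[idx, None] * diag
        try:
            step = np.linalg.solve(Hd, -grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.einsum("vij,vj->vi", np.linalg.pinv(Hd), grad)

        trial = th_a + step
        obj_t, pred_t, r_t = objective_subset(trial, Y[idx], q, positivity)
        improved = np.isfinite(obj_t) & (obj_t <= obj[idx])

        acc = idx[improved]
        theta[acc] = trial[improved]
        pred[acc] = pred_t[improved]
        resid[acc] = r_t[improved]
        decrease = obj[acc] - obj_t[improved]
        newly = decrease <= rtol * np.maximum(obj[acc], 1e-300)
        obj[acc] = obj_t[improved]
        lam[acc] = np.maximum(lam[acc] * 0.3, 1e-12)
        converged[acc[newly]] = True
        active[acc[newly]] = False

        rej = idx[~improved]
        lam[rej] *= 5.0
        stalled = rej[lam[rej] > 1e12]
        converged[stalled] = True                       # cannot improve further
        active[stalled] = False

    s0_fit, d_fit = unpack_theta(theta)
    finite = np.isfinite(d_fit).all(axis=1) & np.isfinite(s0_fit)

    shape = data.shape[:3]
    tensors = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    tensors[mask] = np.where(finite[:, None], d_fit, 0.0)
    s0[mask] = np.where(finite, s0_fit, 0.0)
    valid[mask] = finite & converged
    clamped = init.clamped if init.clamped is not None else None
    return TensorField(tensors, s0, mask, valid, dims, origin, clamped,
                       meta={"method": "nonlinear", "positivity": positivity,
                             "objective": obj.copy()})


def objective_subset(th, Y, q, positivity):
    if positivity:
        s0 = np.exp(np.clip(th[:, 0], -300, 300))
        d = _chol_pack(th[:, 1:])
    else:
        s0 = th[:, 0]
        d = th[:, 1:]
    pred = s0[:, None] * np.exp(-np.clip(d @ q.T, -300, 300))
    r = pred - Y
    return np.einsum("vn,vn->v", r, r), pred, r


# ---------------------------------------------------------------------------
# scalar maps
# ---------------------------------------------------------------------------

def tensors_from_eigen(eigenvalues, eigenvectors) -> np.ndarray:
    """Assemble D = V diag(λ) Vᵀ from eigenvalues (…,3) and columns of V."""
    w = np.asarray(eigenvalues, dtype=float)
    V = np.asarray(eigenvectors, dtype=float)
    return np.einsum("...ik,...k,...jk->...ij", V, w, V)


_SYM_TOL = 1e-10


def scalar_maps(tensor_field) -> ScalarMaps:
    """Eigenvalue scalar maps (λ1 ≥ λ2 ≥ λ3, MD, FA) of a tensor field.

    Accepts a :class:`TensorField` or a raw (..., 3, 3) array of symmetric
    matrices (asymmetric input raises).  FA is flagged invalid where all
    eigenvalues vanish (the formula is undefined there).
    """
    if isinstance(tensor_field, TensorField):
        mats = tensor_field.matrices()
        domain = tensor_field.valid & tensor_field.mask
        dims, origin = tensor_field.voxel_dims, tensor_field.origin
        grid_shape = mats.shape[:-2]
    else:
        mats = np.asarray(tensor_field, dtype=float)
        if mats.shape[-2:] != (3, 3):
            raise ValueError("expected (..., 3, 3) tensors")
        asym = np.abs(mats - np.swapaxes(mats, -1, -2))
        scale = np.maximum(np.abs(mats).max(axis=(-1, -2), keepdims=True), 1e-300)
        if np.any(asym > _SYM_TOL * scale):
            raise ValueError("asymmetric tensor input: tensors must be symmetric")
        domain = np.ones(mats.shape[:-2], dtype=bool)
        dims, origin = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
        grid_shape = mats.shape[:-2]

    w = np.linalg.eigvalsh(mats)[..., ::-1]            # descending
    l1, l2, l3 = w[..., 0], w[..., 1], w[..., 2]
    md = (l1 + l2 + l3) / 3.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    degenerate = den == 0
    fa = np.sqrt(1.5) * np.sqrt(num / np.where(degenerate, 1.0, den))
    valid = domain & ~degenerate

    def _mask(a, dom):
        out = np.where(dom, a, np.nan)
        return out

    return ScalarMaps(
        lambda1=_mask(l1, domain), lambda2=_mask(l2, domain),
        lambda3=_mask(l3, domain), md=_mask(md, domain),
        fa=_mask(fa, valid), valid=valid,
        voxel_dims=dims, origin=origin,
    )
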