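"""Optical-flow estimation: local least-squares (Lucas–Kanade style) flow on
a grid, then a smooth dense field by ridge projection onto a low-dimensional
orthonormal basis of vector fields.

The local solver enforces the flow constraint Ix·vx + Iy·vy + It = 0 in a
least-squares sense over a square window, refined over a Gaussian image
pyramid with warping iterations so that shifts of several pixels are
recovered to subpixel accuracy. Grid cells whose gradient normal matrix is
ill-conditioned (textureless) are marked invalid; an optional significance
gate additionally rejects cells whose vector is indistinguishable from zero
given the local fit residual.

When no training corpus of flow fields is available, the smoothing basis is
analytic: 2D polynomial fields of degree <= 2 per component, orthonormalized
over the grid. ``fit_basis`` learns a basis by PCA when training fields are
supplied.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import FlowParams
from .datatypes import FlowBasis, ImageStack, ParameterError, VectorField

__all__ = [
    "sparse_flow",
    "dense_lk_flow",
    "fit_basis",
    "polynomial_basis",
    "smooth_field",
    "flow_pipeline",
    "sparse_fields",
]


def _window_sum(a: np.ndarray, window: int) -> np.ndarray:
    return ndimage.uniform_filter(a, size=window, mode="nearest") * float(window**2)


def _lk_increment(a: np.ndarray, b: np.ndarray, window: int):
    """One linearized LK solve. Returns (dvx, dvy, lam_min, M, bvec)."""
    mean = 0.5 * (a + b)
    Iy, Ix = np.gradient(mean)
    It = b - a
    Mxx = _window_sum(Ix * Ix, window)
    Mxy = _window_sum(Ix * Iy, window)
    Myy = _window_sum(Iy * Iy, window)
    bx = _window_sum(Ix * It, window)
    by = _window_sum(Iy * It, window)
    det = Mxx * Myy - Mxy * Mxy
    trace = Mxx + Myy
    lam_min = 0.5 * (trace - np.sqrt((Mxx - Myy) ** 2 + 4.0 * Mxy * Mxy))
    safe = det > np.finfo(float).tiny * np.maximum(trace, 1.0) ** 2
    inv_det = np.where(safe, 1.0 / np.where(safe, det, 1.0), 0.0)
    dvx = -(Myy * bx - Mxy * by) * inv_det
    dvy = -(Mxx * by - Mxy * bx) * inv_det
    # cap wild increments from near-singular systems
    cap = float(window)
    np.clip(dvx, -cap, cap, out=dvx)
    np.clip(dvy, -cap, cap, out=dvy)
    return dvx, dvy, lam_min, (Mxx, Mxy, Myy), It


def _warp(b: np.ndarray, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    h, w = b.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    # cubic interpolation: linear warping leaves flow-dependent intensity
    # bias that the Gauss-Newton iterations then chase
    return ndimage.map_coordinates(b, [yy + vy, xx + vx], order=3, mode="nearest")


def _downscale(a: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(a, 1.0, mode="nearest")[::2, ::2]


def dense_lk_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 9,
    n_levels: int = 3,
    n_iter: int = 3,
    smooth_sigma: float = 1.5,
):
    """Per-pixel pyramidal LK flow.

    Returns ``(vx, vy, lam_min, sig)``: the flow field (px/frame, motion of
    content from frame_a to frame_b), the smallest eigenvalue of the local
    gradient normal matrix, and the motion-significance ratio
    (RSS_zero − RSS_flow) / RSS_flow of the windowed warp residuals.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError("frames must share one shape")
    if window > min(a.shape):
        raise ParameterError(
            f"window {window} exceeds frame size {a.shape}"
        )
    # build pyramid (coarsest last); never shrink below ~2x window
    pyr = [(a, b)]
    for _ in range(n_levels - 1):
        pa, pb = pyr[-1]
        if min(pa.shape) < 2 * window:
            break
        pyr.append((_downscale(pa), _downscale(pb)))

    vx = np.zeros_like(pyr[-1][0])
    vy = np.zeros_like(vx)
    for level in range(len(pyr) - 1, -1, -1):
        pa, pb = pyr[level]
        if vx.shape != pa.shape:
            zy = pa.shape[0] / vx.shape[0]
            zx = pa.shape[1] / vx.shape[1]
            vx = ndimage.zoom(vx, (zy, zx), order=1) * 2.0
            vy = ndimage.zoom(vy, (zy, zx), order=1) * 2.0
        for _ in range(n_iter):
            bw = _warp(pb, vx, vy)
            dvx, dvy, lam_min, M, _ = _lk_increment(pa, bw, window)
            vx = vx + dvx
            vy = vy + dvy
            if smooth_sigma > 0:
                # damp window-scale oscillation of the per-pixel increments
                vx = ndimage.gaussian_filter(vx, smooth_sigma, mode="nearest")
                vy = ndimage.gaussian_filter(vy, smooth_sigma, mode="nearest")

    if len(pyr) > 1:
        # Coarse levels can leak large motions into static regions, where
        # the short-correlation texture leaves fine-level refinement stuck.
        # Guard with a zero-initialized single-scale hypothesis and keep,
        # per pixel, whichever flow warps frame_b onto frame_a better.
        sx = np.zeros_like(a)
        sy = np.zeros_like(a)
        for _ in range(n_iter):
            bw = _warp(b, sx, sy)
            dvx, dvy, _, _, _ = _lk_increment(a, bw, window)
            sx = sx + dvx
            sy = sy + dvy
            if smooth_sigma > 0:
                sx = ndimage.gaussian_filter(sx, smooth_sigma, mode="nearest")
                sy = ndimage.gaussian_filter(sy, smooth_sigma, mode="nearest")
        res_pyr = _window_sum((_warp(b, vx, vy) - a) ** 2, window)
        res_single = _window_sum((_warp(b, sx, sy) - a) ** 2, window)
        take_single = res_single < res_pyr
        vx = np.where(take_single, sx, vx)
        vy = np.where(take_single, sy, vy)

    # final diagnostics at full resolution
    bw = _warp(b, vx, vy)
    _, _, lam_min, _, _ = _lk_increment(a, bw, window)
    rss_v = _window_sum((bw - a) ** 2, window)
    rss_0 = _window_sum((b - a) ** 2, window)
    # motion significance: fractional reduction of the warp residual by the
    # fitted flow relative to the zero-flow hypothesis. Self-calibrating
    # (no noise model needed): ~0 for static windows, >> 1 where real
    # motion is explained.
    sig = (rss_0 - rss_v) / np.maximum(rss_v, np.finfo(float).tiny)
    return vx, vy, lam_min, sig


def grid_centers(shape: tuple[int, int], grid_step: int) -> tuple[np.ndarray, np.ndarray]:
    """Grid-cell centre coordinates (xs, ys) for a frame of given shape."""
    h, w = shape
    xs = np.arange(grid_step // 2, w, grid_step)
    ys = np.arange(grid_step // 2, h, grid_step)
    return xs, ys


def sparse_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 9,
    grid_step: int = 4,
    n_levels: int = 3,
    n_iter: int = 3,
    smooth_sigma: float = 1.5,
    min_eig_scale: float = 1e-2,
    min_significance: float | None = None,
    frame_pair: tuple[int, int] = (0, 1),
) -> VectorField:
    """Local least-squares flow sampled at grid-cell centres.

    Cells where the smallest eigenvalue of the gradient normal matrix falls
    below ``min_eig_scale * window**2`` (textureless / rank-deficient) are
    invalid. With ``min_significance`` set, cells whose fitted flow does not
    reduce the local warp residual by at least that factor relative to the
    zero-flow hypothesis are also invalid (static or unexplained windows).
    """
    vx, vy, lam_min, sig = dense_lk_flow(
        frame_a, frame_b, window=window, n_levels=n_levels, n_iter=n_iter,
        smooth_sigma=smooth_sigma,
    )
    xs, ys = grid_centers(vx.shape, grid_step)
    gvx = vx[np.ix_(ys, xs)]
    gvy = vy[np.ix_(ys, xs)]
    glam = lam_min[np.ix_(ys, xs)]
    gsig = sig[np.ix_(ys, xs)]
    valid = (glam >= min_eig_scale * window**2) & np.isfinite(gvx) & np.isfinite(gvy)
    if min_significance is not None:
        valid &= gsig >= min_significance
    gvx = np.where(np.isfinite(gvx), gvx, 0.0)
    gvy = np.where(np.isfinite(gvy), gvy, 0.0)
    return VectorField(
        frame_pair=frame_pair, grid_x=xs, grid_y=ys, vx=gvx, vy=gvy, valid=valid
    )


def fit_basis(training_fields: list[VectorField], K: int) -> FlowBasis:
    """Principal-component basis of vectorized training flow fields.

    The mean field is removed; the top-K right singular vectors form the
    (orthonormal) components. Explained-variance fractions are reported.
    """
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    if len(training_fields) < 1:
        raise ParameterError("need at least one training field")
    shape = training_fields[0].vx.shape
    for f in training_fields:
        if f.vx.shape != shape:
            raise ParameterError("training fields must share one grid")
    X = np.stack(
        [np.concatenate([f.vx.ravel(), f.vy.ravel()]) for f in training_fields]
    )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if K > rank:
        raise ParameterError(
            f"K={K} exceeds the rank {rank} of the training set"
        )
    power = s**2
    explained = power[:K] / power.sum()
    return FlowBasis(
        grid_shape=shape,
        components=Vt[:K],
        mean=mean,
        explained_variance=explained,
    )


def polynomial_basis(
    grid_shape: tuple[int, int], degree: int = 2
) -> FlowBasis:
    """Analytic default basis: per-component 2D polynomials up to ``degree``,
    orthonormalized over the grid (QR). Degree 2 gives K = 12.

    Used when no training corpus of flow fields is available; the basis
    spans uniform translation, shear/divergence-like gradients and gentle
    quadratic variation for each component.
    """
    ny, nx = grid_shape
    if ny < 1 or nx < 1:
        raise ParameterError("grid must be non-empty")
    xn = np.linspace(-1.0, 1.0, nx) if nx > 1 else np.zeros(1)
    yn = np.linspace(-1.0, 1.0, ny) if ny > 1 else np.zeros(1)
    Y, X = np.meshgrid(yn, xn, indexing="ij")
    monomials = []
    for d in range(degree + 1):
        for j in range(d + 1):
            monomials.append((X ** (d - j)) * (Y**j))
    g = ny * nx
    cols = []
    for m in monomials:  # vx components first, then vy, degree-ordered
        cols.append(np.concatenate([m.ravel(), np.zeros(g)]))
    for m in monomials:
        cols.append(np.concatenate([np.zeros(g), m.ravel()]))
    # interleave by degree so truncation at any K keeps low-order terms first
    order = []
    nm = len(monomials)
    for i in range(nm):
        order.extend([i, nm + i])
    A = np.stack([cols[i] for i in order], axis=1)
    Q, R = np.linalg.qr(A)
    # fix signs for reproducibility
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return FlowBasis(
        grid_shape=grid_shape,
        components=Q.T,
        mean=np.zeros(2 * g),
        explained_variance=None,
    )


def smooth_field(
    sparse: VectorField, basis: FlowBasis, ridge: float = 1e-3
) -> VectorField:
    """Ridge-regularized projection of the valid sparse vectors onto the
    basis; returns the reconstructed dense field on the full grid.
    """
    if sparse.vx.shape != basis.grid_shape:
        raise ParameterError("sparse field and basis grids differ")
    if ridge < 0:
        raise ParameterError("ridge must be >= 0")
    mask = sparse.valid.ravel()
    n_valid = int(mask.sum())
    if n_valid < basis.K:
        raise ParameterError(
            f"only {n_valid} valid cells for K={basis.K} basis components; "
            "use a smaller K"
        )
    rows = np.concatenate([mask, mask])
    A = basis.components[:, rows].T  # (2*n_valid, K)
    y = np.concatenate([sparse.vx.ravel()[mask], sparse.vy.ravel()[mask]])
    y = y - basis.mean[rows]
    lhs = A.T @ A + ridge * np.eye(basis.K)
    coef = np.linalg.solve(lhs, A.T @ y)
    recon = basis.mean + basis.components.T @ coef
    g = basis.grid_shape[0] * basis.grid_shape[1]
    return VectorField(
        frame_pair=sparse.frame_pair,
        grid_x=sparse.grid_x,
        grid_y=sparse.grid_y,
        vx=recon[:g].reshape(basis.grid_shape),
        vy=recon[g:].reshape(basis.grid_shape),
        valid=np.ones(basis.grid_shape, dtype=bool),
    )


def _margin_invalidate(field: VectorField, margin_px: float, shape: tuple[int, int]) -> None:
    """Invalidate grid cells whose window support may touch border fill."""
    if margin_px <= 0:
        return
    h, w = shape
    bad_x = (field.grid_x < margin_px) | (field.grid_x >= w - margin_px)
    bad_y = (field.grid_y < margin_px) | (field.grid_y >= h - margin_px)
    field.valid[bad_y, :] = False
    field.valid[:, bad_x] = False


def sparse_fields(
    stack: ImageStack,
    params: FlowParams | None = None,
    margin_px: float = 0.0,
) -> list[VectorField]:
    """Sparse flow for every consecutive frame pair of a registered stack."""
    params = (params or FlowParams()).validate()
    if stack.n_frames < 2:
        raise ParameterError("need >= 2 frames for flow")
    out = []
    for t in range(stack.n_frames - 1):
        f = sparse_flow(
            stack.frames[t],
            stack.frames[t + 1],
            window=params.window,
            grid_step=params.grid_step,
            n_levels=params.n_levels,
            n_iter=params.n_iter,
            smooth_sigma=params.smooth_sigma,
            min_eig_scale=params.min_eig_scale,
            min_significance=params.min_significance,
            frame_pair=(t, t + 1),
        )
        _margin_invalidate(f, margin_px, stack.shape)
        out.append(f)
    return out


def flow_pipeline(
    stack: ImageStack,
    params: FlowParams | None = None,
    basis: FlowBasis | None = None,
    margin_px: float = 0.0,
    return_sparse: bool = False,
):
    """Sparse flow + basis smoothing for every consecutive frame pair.

    Without a supplied basis the analytic polynomial basis is used. A frame
    pair with fewer valid sparse cells than K (e.g. a static, noise-free
    stack after the significance gate) yields the basis mean field (all
    zeros for the analytic basis) rather than an error.
    """
    params = (params or FlowParams()).validate()
    sparse = sparse_fields(stack, params, margin_px=margin_px)
    shape = sparse[0].vx.shape
    if basis is None:
        basis = polynomial_basis(shape, degree=params.poly_degree)
        if basis.K > params.K:
            basis = FlowBasis(
                grid_shape=basis.grid_shape,
                components=basis.components[: params.K],
                mean=basis.mean,
                explained_variance=None,
            )
    dense = []
    g = shape[0] * shape[1]
    for f in sparse:
        if f.n_valid >= basis.K:
            dense.append(smooth_field(f, basis, ridge=params.ridge))
        else:
            dense.append(
                VectorField(
                    frame_pair=f.frame_pair,
                    grid_x=f.grid_x,
                    grid_y=f.grid_y,
                    vx=basis.mean[:g].reshape(shape).copy(),
                    vy=basis.mean[g:].reshape(shape).copy(),
                    valid=np.ones(shape, dtype=bool),
                )
            )
    if return_sparse:
        return dense, sparse
    return dense
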