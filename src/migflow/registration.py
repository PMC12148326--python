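"""Stack stabilization: grayscale conversion, translation registration,
and optional landmark-based affine warping.

Stabilization is translation-only, estimated per frame against a reference
frame by phase cross-correlation with subpixel (upsampled-spectrum)
refinement. Affine warping is available when paired landmark lists are
supplied; it is a per-frame least-squares affine fit resampled with
bilinear interpolation. Out-of-field pixels are filled with a constant 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp

from .datatypes import ImageStack, ParameterError, RegistrationResult

# ITU-R BT.709 luminance weights (as used by scikit-image's rgb2gray)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def to_grayscale(stack: ImageStack) -> ImageStack:
    """Collapse an RGB stack to single-channel luminance.

    Single-channel input is passed through unchanged. The weights sum to 1,
    so a gray RGB frame keeps its value.
    """
    if not stack.is_multichannel:
        return stack
    if stack.frames.shape[-1] != 3:
        raise ParameterError(
            f"expected 1 or 3 channels, got {stack.frames.shape[-1]}"
        )
    gray = stack.frames.astype(np.float64) @ _LUMA
    return ImageStack(gray, stack.pixel_size, stack.frame_interval)


def _foreground_threshold(frame: np.ndarray) -> float:
    """Robust brightness threshold separating bright moving objects from
    the static background: median + 3 scaled MADs."""
    med = np.median(frame)
    mad = np.median(np.abs(frame - med))
    return float(med + 3.0 * 1.4826 * mad)


def _subpixel_refine(
    ref: np.ndarray, moving: np.ndarray, static: np.ndarray, n_iter: int = 2
) -> np.ndarray:
    """Residual subpixel translation (dx, dy) of ``moving`` content relative
    to ``ref``, from a global gradient least-squares fit over ``static``
    pixels only."""
    d = np.zeros(2)
    Iy, Ix = np.gradient(ref)
    for _ in range(n_iter):
        mov = (
            moving
            if not d.any()
            else ndimage.shift(moving, (-d[1], -d[0]), order=1, mode="nearest")
        )
        It = mov - ref
        m = static
        A = np.array(
            [
                [np.sum(Ix[m] * Ix[m]), np.sum(Ix[m] * Iy[m])],
                [np.sum(Ix[m] * Iy[m]), np.sum(Iy[m] * Iy[m])],
            ]
        )
        b = np.array([np.sum(Ix[m] * It[m]), np.sum(Iy[m] * It[m])])
        if np.linalg.cond(A) > 1e12:
            break
        step = -np.linalg.solve(A, b)
        d += step  # content motion ref -> moving, (dx, dy)... see below
        if np.hypot(*step) < 1e-3:
            break
    return d


def stabilize(
    stack: ImageStack,
    reference: int = 0,
    upsample_factor: int = 10,
    suppress_foreground: bool = True,
) -> RegistrationResult:
    """Estimate and remove per-frame translation relative to ``reference``.

    ``offsets[t]`` is the estimated (dx, dy) displacement of frame ``t``'s
    content relative to the reference frame; each frame is resampled by the
    negative of its offset (bilinear, constant-0 fill).

    With ``suppress_foreground`` (default), bright moving objects (the
    migrating cells) are excluded from the translation estimate so that the
    stabilizer anchors on static tissue rather than on the cohort's own
    motion: the integer part comes from masked normalized cross-correlation
    and the subpixel part from a gradient least-squares fit over the static
    pixels. Without it, translation is estimated by plain phase
    cross-correlation of spectra with upsampled subpixel refinement.

    An all-constant frame has no registrable signal: its offset is reported
    as (0, 0) and a warning is recorded.
    """
    if stack.is_multichannel:
        raise ParameterError("stabilize expects a single-channel stack")
    if stack.n_frames < 2:
        raise ParameterError("stabilize needs at least 2 frames")
    if not (0 <= reference < stack.n_frames):
        raise ParameterError(f"reference frame {reference} out of range")

    frames = stack.frames.astype(np.float64)
    ref = frames[reference]
    warnings: list[str] = []
    offsets = np.zeros((stack.n_frames, 2))
    out = np.empty_like(frames)
    ref_thr = _foreground_threshold(ref) if suppress_foreground else np.inf
    ref_mask = ref < ref_thr
    for t in range(stack.n_frames):
        if t == reference:
            out[t] = frames[t]
            continue
        if np.ptp(frames[t]) == 0 or np.ptp(ref) == 0:
            warnings.append(f"frame {t}: constant image, offset set to (0, 0)")
            out[t] = frames[t]
            continue
        if suppress_foreground and ref_mask.mean() > 0.05:
            mov_mask = frames[t] < _foreground_threshold(frames[t])
            with np.errstate(invalid="ignore"):
                ishift = phase_cross_correlation(
                    ref, frames[t], reference_mask=ref_mask, moving_mask=mov_mask
                )
            ishift = ishift[0] if isinstance(ishift, tuple) else ishift
            rolled = np.roll(
                frames[t], (int(ishift[0]), int(ishift[1])), axis=(0, 1)
            )
            static = ref_mask & np.roll(mov_mask, (int(ishift[0]), int(ishift[1])),
                                        axis=(0, 1))
            # integer content displacement is -ishift; refine the remainder
            sub = _subpixel_refine(ref, rolled, static)
            dx = -float(ishift[1]) + sub[0]
            dy = -float(ishift[0]) + sub[1]
        else:
            shift, _, _ = phase_cross_correlation(
                ref, frames[t], upsample_factor=upsample_factor,
                normalization="phase",
            )
            # shift aligns frame t onto the reference; the content moved
            # by -shift relative to the reference.
            dx, dy = -shift[1], -shift[0]
        offsets[t] = (dx, dy)
        out[t] = ndimage.shift(frames[t], (-dy, -dx), order=1, mode="constant",
                               cval=0.0)

    reg = ImageStack(out, stack.pixel_size, stack.frame_interval)
    return RegistrationResult(stack=reg, offsets=offsets, reference=reference,
                              warnings=warnings)


def rebase_offsets(offsets: np.ndarray, new_reference: int) -> np.ndarray:
    """Re-express translation offsets relative to another reference frame."""
    return offsets - offsets[new_reference]


def fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares affine fit mapping ``src`` (x, y) points onto ``dst``.

    Returns the 3x3 homogeneous matrix. Requires >= 3 non-collinear pairs.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ParameterError("landmarks must be matching (N, 2) arrays")
    if src.shape[0] < 3:
        raise ParameterError(f"need >= 3 landmark pairs, got {src.shape[0]}")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ParameterError("landmark points are collinear")
    X = np.column_stack([src, np.ones(src.shape[0])])
    beta, *_ = np.linalg.lstsq(X, dst, rcond=None)  # (3, 2)
    params = np.eye(3)
    params[:2, :] = beta.T
    return params


def affine_warp(
    stack: ImageStack,
    landmarks: dict[int, tuple[np.ndarray, np.ndarray]],
) -> ImageStack:
    """Warp selected frames by per-frame landmark-fitted affine transforms.

    ``landmarks`` maps a frame index to a pair ``(src, dst)`` of matching
    (N, 2) point arrays in (x, y) pixel coordinates: the fitted transform A
    maps src -> dst and the frame is resampled so that content at ``src``
    lands at ``dst``. Frames without landmarks pass through unchanged.
    """
    if stack.is_multichannel:
        raise ParameterError("affine_warp expects a single-channel stack")
    out = stack.frames.astype(np.float64).copy()
    for t, (src, dst) in landmarks.items():
        if not (0 <= t < stack.n_frames):
            raise ParameterError(f"landmark frame {t} out of range")
        try:
            params = fit_affine(src, dst)
        except ParameterError as exc:
            raise ParameterError(f"frame {t}: {exc}") from exc
        tform = AffineTransform(matrix=params)
        out[t] = warp(
            out[t], inverse_map=tform.inverse, order=1, mode="constant",
            cval=0.0, preserve_range=True,
        )
    return ImageStack(out, stack.pixel_size, stack.frame_interval)
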