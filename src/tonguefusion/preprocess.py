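"""Bring a thermal/visible tongue-image pair onto a common grid.

The two modalities come off different cameras (thermal 320x240 px, visible
390x280 px RGB) with a small unknown rigid misalignment (translation plus a
rotation bounded by 5 degrees).  This module provides grayscale conversion,
bilinear resizing, rigid registration by exhaustive normalized-correlation
search, and extraction of the central 50x50 region of interest on which
texture features are computed.

Index conventions, stated once for the whole package: images are 2-D numpy
arrays indexed ``(row, col)``, 0-based, with intensities in ``[0, 255]``
(8-bit convertible, held as floats internally).  A shape of ``(240, 320)``
is the 320x240-pixel (width x height) thermal frame.  In rigid transforms,
``dx`` shifts along columns (x), ``dy`` along rows (y), and positive
``theta`` rotates the image content counterclockwise about the frame
center; the transform maps content points as ``p_out = R(p_in - c) + c + t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "RigidTransform",
    "apply_rigid",
    "invert_rigid",
    "to_grayscale",
    "resize_to",
    "register_rigid",
    "extract_central_roi",
]

#: ITU-R BT.601 luminance weights (the classic rgb2gray / PIL "L"
#: convention); they sum to exactly 1, so channel-equal grays pass through.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class RigidTransform:
    """A translation + rotation, ``dx``/``dy`` in pixels, ``theta`` in degrees."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def inverse(self) -> "RigidTransform":
        return RigidTransform(*invert_rigid(self.dx, self.dy, self.theta))


def _rot_matrix(theta_deg: float) -> np.ndarray:
    a = np.deg2rad(theta_deg)
    c, s = np.cos(a), np.sin(a)
    # (row, col) plane; positive theta = counterclockwise on screen.
    return np.array([[c, s], [-s, c]])


def apply_rigid(image, dx=0.0, dy=0.0, theta=0.0, order=1, cval=0.0):
    """Rotate ``image`` by ``theta`` about its center, then shift by (dx, dy).

    Out-of-frame pixels are filled with ``cval`` (0 = the black backdrop used
    during acquisition).  Works on 2-D arrays and on (rows, cols, channels)
    stacks, channel by channel.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return np.dstack(
            [apply_rigid(image[..., ch], dx, dy, theta, order, cval)
             for ch in range(image.shape[2])]
        )
    if dx == 0 and dy == 0 and theta == 0:
        return image.copy()
    R = _rot_matrix(theta)
    center = (np.array(image.shape) - 1) / 2.0
    t = np.array([dy, dx], dtype=float)
    # ndimage.affine_transform: input_coords = matrix @ output_coords + offset
    matrix = R.T  # R^{-1}
    offset = center - matrix @ (center + t)
    return ndimage.affine_transform(
        image, matrix, offset=offset, order=order, cval=cval, mode="constant"
    )


def invert_rigid(dx: float, dy: float, theta: float):
    """Exact inverse parameters of a rotate-then-translate rigid transform.

    The inverse of (rotate theta, translate t) is (rotate -theta,
    translate -R(-theta) t) — note the rotated translation, which differs
    from -t by up to ``|t|*theta`` for small angles.
    """
    Rinv = _rot_matrix(-theta)
    tdy, tdx = -(Rinv @ np.array([dy, dx]))
    return float(tdx), float(tdy), float(-theta)


def to_grayscale(image) -> np.ndarray:
    """Convert an RGB image (any float/uint8 scale in [0, 255]) to luminance.

    Uses the BT.601 weights 0.2989 R + 0.5870 G + 0.1140 B.  Single-channel
    input passes through unchanged (as float).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        return image @ w
    raise ValueError(f"expected a 2-D or (rows, cols, 3) array, got {image.shape}")


def resize_to(image, target_height: int, target_width: int) -> np.ndarray:
    """Bilinear resample to exactly ``(target_height, target_width)``."""
    if target_height < 1 or target_width < 1:
        raise ValueError("target dimensions must be >= 1")
    image = np.asarray(image, dtype=float)
    shape = (target_height, target_width) + image.shape[2:]
    if image.shape == shape:
        return image.copy()
    return _sk_resize(image, shape, order=1, preserve_range=True, mode="edge")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _best_shift(rotated: np.ndarray, f0: np.ndarray, f_hat: np.ndarray,
                max_shift: int):
    """Best integer shift of ``rotated`` onto the fixed image, via FFT
    cross-correlation of zero-mean images, restricted to |shift| <= max_shift.

    Returns (dy, dx, score) with a circular-correlation NCC score.
    """
    r0 = rotated - rotated.mean()
    corr = np.fft.irfft2(f_hat * np.conj(np.fft.rfft2(r0)), s=f0.shape)
    shifts = np.arange(-max_shift, max_shift + 1)
    window = corr[np.ix_(shifts % f0.shape[0], shifts % f0.shape[1])]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    norm = np.sqrt((f0 * f0).sum() * (r0 * r0).sum())
    score = window[iy, ix] / norm if norm > 0 else 0.0
    return int(shifts[iy]), int(shifts[ix]), float(score)


def register_rigid(moving, fixed, max_shift: int = 12, max_rot: float = 5.0,
                   rot_step: float = 0.5, refine_step: float = 0.1,
                   highpass_sigma: float | None = 2.0):
    """Rigidly align ``moving`` to ``fixed`` by maximizing normalized
    cross-correlation.

    The search is exhaustive: every integer translation within
    ``+/- max_shift`` (evaluated at once through an FFT cross-correlation)
    for every rotation on a ``rot_step`` grid within ``+/- max_rot`` degrees,
    followed by a local rotation refinement at ``refine_step`` resolution.
    The correlation is computed on high-pass-filtered images (original minus
    a Gaussian blur of width ``highpass_sigma``; pass ``None`` to disable):
    the smooth tongue silhouette is nearly rotation-invariant and would
    otherwise swamp the fine texture that actually pins down the rotation.
    The identity transform is always a candidate, so the similarity of the
    returned registration never falls below that of the unregistered pair.

    Returns ``(RigidTransform, registered_image)``; applying the transform
    to ``moving`` yields ``registered_image``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {fixed.shape}")

    if highpass_sigma:
        moving_s = moving - ndimage.gaussian_filter(moving, highpass_sigma)
        fixed_s = fixed - ndimage.gaussian_filter(fixed, highpass_sigma)
    else:
        moving_s, fixed_s = moving, fixed
    f0 = fixed_s - fixed_s.mean()
    f_hat = np.fft.rfft2(f0)

    def evaluate(theta):
        rot = apply_rigid(moving_s, 0, 0, theta) if theta != 0 else moving_s
        dy, dx, score = _best_shift(rot, f0, f_hat, max_shift)
        return score, (dx, dy, theta)

    thetas = np.arange(-max_rot, max_rot + rot_step / 2, rot_step)
    coarse = [evaluate(float(t)) for t in thetas]
    best_score, (dx, dy, theta) = max(coarse, key=lambda r: r[0])

    if refine_step and refine_step < rot_step:
        fine = np.arange(theta - rot_step + refine_step,
                         theta + rot_step - refine_step / 2, refine_step)
        fine = fine[np.abs(fine) <= max_rot + 1e-9]
        for t in fine:
            score, params = evaluate(float(t))
            if score > best_score:
                best_score, (dx, dy, theta) = score, params

    candidate = apply_rigid(moving, dx, dy, theta)
    # Guarantee similarity(registered, fixed) >= similarity(moving, fixed)
    # under the exact (non-circular) Pearson measure.
    if _pearson(candidate, fixed) >= _pearson(moving, fixed):
        return RigidTransform(float(dx), float(dy), float(theta)), candidate
    return RigidTransform(0.0, 0.0, 0.0), moving.copy()


def extract_central_roi(image, size: int = 50, center=None) -> np.ndarray:
    """Extract a ``size`` x ``size`` square centered at ``(m//2, n//2)``.

    ``center`` overrides the automatic placement with an explicit
    ``(row, col)``.  The ROI must fit entirely inside the frame.
    """
    image = np.asarray(image)
    m, n = image.shape[:2]
    if m < size or n < size:
        raise ValueError(f"image {m}x{n} smaller than {size}x{size} ROI")
    r0, c0 = (m // 2, n // 2) if center is None else center
    top, left = r0 - size // 2, c0 - size // 2
    if top < 0 or left < 0 or top + size > m or left + size > n:
        raise ValueError("ROI extends outside the image")
    return image[top:top + size, left:left + size, ...]
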