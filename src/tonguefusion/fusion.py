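"""Wavelet-domain fusion of co-registered thermal and visible tongue images.

Each image is decomposed with a two-level Daubechies-2 (db2) discrete wavelet
transform into one deepest-level approximation band plus three detail bands
(horizontal / vertical / diagonal) per level.  A *fusion rule* is an ordered
pair of elementwise operators, each drawn from {mean, max, min}: the first is
applied to the two approximation bands, the second to every detail band at
every level.  The fused image is the inverse transform of the combined
pyramid.  There are exactly nine such rules; "mean-max" (average the
low-frequency content, keep the stronger high-frequency detail) is the one
usually preferred for thermal/visible tongue fusion.

Fusion operates on float-valued coefficients of float images in [0, 255];
clipping and rounding to 8-bit happen only at export (:func:`to_uint8`).
Boundary handling uses symmetric (half-sample) signal extension, which keeps
constant images exactly constant through the analysis/synthesis pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "FusionRule",
    "WaveletPyramid",
    "enumerate_rules",
    "decompose",
    "combine",
    "combine_select",
    "reconstruct",
    "fuse",
    "to_uint8",
]

_OPS = {
    "mean": lambda a, b: (a + b) / 2.0,
    "max": np.maximum,
    "min": np.minimum,
}


@dataclass(frozen=True)
class FusionRule:
    """Ordered operator pair: ``approx_op`` for the approximation band,
    ``detail_op`` for all detail bands."""

    approx_op: str
    detail_op: str

    def __post_init__(self):
        for op in (self.approx_op, self.detail_op):
            if op not in _OPS:
                raise ValueError(f"unknown operator {op!r}")

    @property
    def name(self) -> str:
        return f"{self.approx_op}-{self.detail_op}"

    @classmethod
    def from_name(cls, name: str) -> "FusionRule":
        approx_op, _, detail_op = name.partition("-")
        return cls(approx_op, detail_op)


def enumerate_rules() -> list[FusionRule]:
    """All nine rules, in canonical order: approximation operator cycles
    slowest, mean before max before min ("mean-mean", "mean-max", ...)."""
    return [FusionRule(a, d)
            for a, d in itertools.product(("mean", "max", "min"), repeat=2)]


@dataclass
class WaveletPyramid:
    """Multi-level 2-D DWT decomposition of a single image.

    ``details`` runs from the deepest (coarsest) level to level 1, each entry
    a ``(horizontal, vertical, diagonal)`` triple, mirroring the layout of
    ``pywt.wavedec2``.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet: str = "db2"
    mode: str = "symmetric"
    image_shape: tuple[int, int] = (0, 0)

    @property
    def levels(self) -> int:
        return len(self.details)

    def structure(self):
        return (self.wavelet, self.mode, self.image_shape,
                self.approximation.shape,
                tuple(tuple(b.shape for b in lev) for lev in self.details))


def decompose(image, wavelet: str = "db2", levels: int = 2,
              mode: str = "symmetric") -> WaveletPyramid:
    """Multi-level 2-D DWT of a single-channel image."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("decompose expects a single-channel 2-D image")
    max_level = pywt.dwtn_max_level(image.shape, wavelet)
    if levels < 1 or levels > max_level:
        raise ValueError(
            f"image {image.shape} supports at most {max_level} levels of "
            f"{wavelet!r} decomposition, requested {levels}")
    coeffs = pywt.wavedec2(image, wavelet, mode=mode, level=levels)
    return WaveletPyramid(
        approximation=coeffs[0],
        details=[tuple(level) for level in coeffs[1:]],
        wavelet=wavelet,
        mode=mode,
        image_shape=image.shape,
    )


def combine(pyrA: WaveletPyramid, pyrB: WaveletPyramid,
            rule: FusionRule) -> WaveletPyramid:
    """Elementwise coefficient combination of two structurally identical
    pyramids under ``rule``."""
    if pyrA.structure() != pyrB.structure():
        raise ValueError("pyramids are structurally different")
    a_op, d_op = _OPS[rule.approx_op], _OPS[rule.detail_op]
    return WaveletPyramid(
        approximation=a_op(pyrA.approximation, pyrB.approximation),
        details=[tuple(d_op(a, b) for a, b in zip(la, lb))
                 for la, lb in zip(pyrA.details, pyrB.details)],
        wavelet=pyrA.wavelet,
        mode=pyrA.mode,
        image_shape=pyrA.image_shape,
    )


def combine_select(pyr_approx: WaveletPyramid,
                   pyr_detail: WaveletPyramid) -> WaveletPyramid:
    """Source-selection combination: take the whole approximation band from
    one pyramid and all detail bands from the other.

    This is *not* one of the nine elementwise rules; it implements the
    low-frequencies-from-one-modality / high-frequencies-from-the-other
    selection sometimes described for multimodal fusion.
    """
    if pyr_approx.structure() != pyr_detail.structure():
        raise ValueError("pyramids are structurally different")
    return WaveletPyramid(
        approximation=pyr_approx.approximation.copy(),
        details=[tuple(b.copy() for b in lev) for lev in pyr_detail.details],
        wavelet=pyr_approx.wavelet,
        mode=pyr_approx.mode,
        image_shape=pyr_approx.image_shape,
    )


def reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse DWT back to the original image dimensions (float-valued)."""
    coeffs = [pyramid.approximation] + [list(lev) for lev in pyramid.details]
    out = pywt.waverec2(coeffs, pyramid.wavelet, mode=pyramid.mode)
    h, w = pyramid.image_shape
    if h and w:
        if out.shape[0] < h or out.shape[1] < w:
            raise ValueError("corrupted pyramid: reconstruction too small")
        out = out[:h, :w]
    return out


def fuse(imageA, imageB, rule: FusionRule | str = "mean-max",
         wavelet: str = "db2", levels: int = 2,
         mode: str = "symmetric") -> np.ndarray:
    """Fuse two equally sized single-channel images under ``rule``.

    Symmetric in its two image arguments for every rule (all three
    elementwise operators are symmetric).  Returns a float image; use
    :func:`to_uint8` for 8-bit export.
    """
    if isinstance(rule, str):
        rule = FusionRule.from_name(rule)
    imageA = np.asarray(imageA, dtype=float)
    imageB = np.asarray(imageB, dtype=float)
    if imageA.shape != imageB.shape:
        raise ValueError(f"shape mismatch: {imageA.shape} vs {imageB.shape}")
    pyrA = decompose(imageA, wavelet=wavelet, levels=levels, mode=mode)
    pyrB = decompose(imageB, wavelet=wavelet, levels=levels, mode=mode)
    return reconstruct(combine(pyrA, pyrB, rule))


def to_uint8(image) -> np.ndarray:
    """Clip to [0, 255] and round — the 8-bit export step."""
    return np.round(np.clip(np.asarray(image, dtype=float), 0, 255)).astype(
        np.uint8)
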