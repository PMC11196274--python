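"""Statistical texture features of a grayscale tongue ROI.

Ten features per region of interest: five second-order Haralick features
computed from a gray-level co-occurrence matrix (energy, contrast,
correlation, entropy, homogeneity) and five first-order histogram moments of
the raw intensities (mean, variance, standard deviation, skewness, kurtosis).

Conventions (the literature is not uniform, so they are fixed here):

* GLCM — intensities uniformly quantized into ``levels`` bins over [0, 255]
  (default 8), co-occurrences counted at a single ``(drow, dcol)`` offset
  (default ``(0, 1)``: distance 1, angle 0), symmetrized by adding the
  transpose, normalized to probabilities.
* energy = sum p^2 (the angular second moment itself, not its square root);
  entropy in bits (log base 2, with 0 log 0 := 0);
  homogeneity = sum p / (1 + |i - j|).
* first-order moments are population moments; skewness is the standardized
  third moment, kurtosis is *excess* kurtosis (normal -> 0); both are
  defined as 0 for zero-variance input, as is the GLCM correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "GLCM",
    "FeatureVector",
    "compute_glcm",
    "glcm_features",
    "first_order_stats",
    "extract_features",
    "feature_table",
]

#: Canonical column order of a feature table.
FEATURE_NAMES = ("mean", "variance", "energy", "contrast", "correlation",
                 "entropy", "homogeneity", "standard_deviation", "kurtosis",
                 "skewness")


@dataclass
class GLCM:
    probabilities: np.ndarray        # (levels, levels)
    levels: int
    offset: tuple[int, int]
    symmetric: bool
    normalized: bool


@dataclass(frozen=True)
class FeatureVector:
    mean: float
    variance: float
    energy: float
    contrast: float
    correlation: float
    entropy: float
    homogeneity: float
    standard_deviation: float
    kurtosis: float
    skewness: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def quantize(roi, levels: int) -> np.ndarray:
    """Uniformly quantize intensities in [0, 255] into ``levels`` bins."""
    roi = np.clip(np.asarray(roi, dtype=float), 0, 255)
    return np.minimum((roi / 256.0 * levels).astype(int), levels - 1)


def compute_glcm(roi, levels: int = 8, offset: tuple[int, int] = (0, 1),
                 symmetric: bool = True, normed: bool = True,
                 prequantized: bool | None = None) -> GLCM:
    """Gray-level co-occurrence matrix of a single-channel ROI.

    ``prequantized`` controls whether pixel values are treated as gray-level
    indices already in ``[0, levels)`` (no rescaling, the convention of
    skimage's ``graycomatrix``) or as raw [0, 255] intensities to be binned.
    The default ``None`` auto-detects: integer-typed input whose maximum is
    below ``levels`` is taken as level indices.
    """
    roi = np.asarray(roi)
    if roi.ndim != 2:
        raise ValueError("compute_glcm expects a single-channel ROI")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    dr, dc = offset
    if roi.shape[0] <= abs(dr) or roi.shape[1] <= abs(dc):
        raise ValueError(f"ROI {roi.shape} too small for offset {offset}")
    if prequantized is None:
        prequantized = (np.issubdtype(roi.dtype, np.integer)
                        and roi.size > 0 and roi.max() < levels
                        and roi.min() >= 0)
    q = roi.astype(int) if prequantized else quantize(roi, levels)
    # paired slices: a at (r, c), b at (r + dr, c + dc)
    r0, r1 = max(0, -dr), roi.shape[0] - max(0, dr)
    c0, c1 = max(0, -dc), roi.shape[1] - max(0, dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    P = counts.reshape(levels, levels).astype(float)
    if symmetric:
        P = P + P.T
    if normed:
        total = P.sum()
        if total > 0:
            P = P / total
    return GLCM(P, levels, (dr, dc), symmetric, normed)


def glcm_features(glcm: GLCM):
    """(energy, contrast, correlation, entropy, homogeneity) of a normalized
    GLCM, per the standard Haralick definitions."""
    if not glcm.normalized:
        raise ValueError("glcm_features requires a normalized GLCM")
    P = glcm.probabilities
    L = glcm.levels
    i = np.arange(L)[:, None].astype(float)
    j = np.arange(L)[None, :].astype(float)
    energy = float((P ** 2).sum())
    contrast = float((P * (i - j) ** 2).sum())
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(
            (P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0           # flat ROI convention
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    return energy, contrast, correlation, entropy, homogeneity


def first_order_stats(roi):
    """(mean, variance, standard_deviation, skewness, kurtosis) of the raw
    pixel intensities (population moments, excess kurtosis)."""
    roi = np.asarray(roi, dtype=float)
    if roi.size == 0:
        raise ValueError("empty ROI")
    mean = float(roi.mean())
    centered = roi - mean
    m2 = float((centered ** 2).mean())
    variance = m2
    std = float(np.sqrt(m2))
    if m2 > 0:
        skewness = float((centered ** 3).mean() / m2 ** 1.5)
        kurtosis = float((centered ** 4).mean() / m2 ** 2 - 3.0)
    else:
        skewness = 0.0
        kurtosis = 0.0
    return mean, variance, std, skewness, kurtosis


def extract_features(roi, levels: int = 8, offset: tuple[int, int] = (0, 1),
                     symmetric: bool = True) -> FeatureVector:
    """Assemble the 10-feature vector of a grayscale ROI."""
    mean, variance, std, skewness, kurtosis = first_order_stats(roi)
    glcm = compute_glcm(roi, levels=levels, offset=offset,
                        symmetric=symmetric, normed=True)
    energy, contrast, correlation, entropy, homogeneity = glcm_features(glcm)
    return FeatureVector(
        mean=mean, variance=variance, energy=energy, contrast=contrast,
        correlation=correlation, entropy=entropy, homogeneity=homogeneity,
        standard_deviation=std, kurtosis=kurtosis, skewness=skewness,
    )


def feature_table(rois, index=None, **kwargs) -> pd.DataFrame:
    """Feature vectors of several ROIs as a DataFrame in canonical column
    order (one row per ROI)."""
    rows = [extract_features(roi, **kwargs).as_dict() for roi in rois]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=index)
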