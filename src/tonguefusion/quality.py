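"""Image-quality metrics for fusion assessment and fusion-rule selection.

Nine full-reference metrics between a processed image X and a reference Y,
computed on float images before any 8-bit rounding:

=====  ==============================================================
mse    mean squared error, (1/mn) sum (X - Y)^2
psnr   10 log10(p^2 / MSE), p the peak intensity (255); +inf when X = Y
snr    10 log10(sum Y^2 / sum (X - Y)^2); +inf when X = Y
nae    normalized absolute error, sum |X - Y| / sum X
ncc    normalized cross-correlation, sum X Y / sum X^2 (1 when X = Y)
ad     average (signed) difference, (1/mn) sum (X - Y); ideal 0
md     maximum absolute difference, max |X - Y|
sc     structural content, sum X^2 / sum Y^2
ssim   structural similarity, evaluated *globally* — one mean/variance/
       covariance triple over the whole image (a sliding-window mean-SSIM
       is available via ``ssim(..., windowed=True)`` but is not the
       default, since rule selection here uses the single-statistic form)
=====  ==============================================================

NCC and NAE use ratio-of-sums denominators, which makes both scale-free and
pins NCC at exactly 1 for identical images.  The fusion-rule selector fuses
every image pair under every candidate rule and ranks rules by minimum mean
MSE (ties broken by maximum mean PSNR, then canonical rule order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import FusionRule, enumerate_rules, fuse
from .preprocess import register_rigid, resize_to, to_grayscale

__all__ = [
    "METRIC_NAMES",
    "QualityConfig",
    "QualityReport",
    "mse", "psnr", "snr", "nae", "ncc", "ad", "md", "sc", "ssim",
    "all_metrics",
    "quality_report",
    "select_best_rule",
]

METRIC_NAMES = ("mse", "psnr", "snr", "nae", "ncc", "ad", "md", "sc", "ssim")


@dataclass(frozen=True)
class QualityConfig:
    """Peak intensity and SSIM regularizers (defaults for 8-bit images)."""

    peak: float = 255.0
    ssim_c1: float = field(default=(0.01 * 255.0) ** 2)
    ssim_c2: float = field(default=(0.03 * 255.0) ** 2)

    def __post_init__(self):
        if self.peak <= 0 or self.ssim_c1 <= 0 or self.ssim_c2 <= 0:
            raise ValueError("peak, c1, c2 must all be positive")


def _pair(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    return X, Y


def mse(X, Y) -> float:
    X, Y = _pair(X, Y)
    return float(((X - Y) ** 2).mean())


def psnr(X, Y, config: QualityConfig = QualityConfig()) -> float:
    err = mse(X, Y)
    if err == 0:
        return math.inf
    return float(10.0 * np.log10(config.peak ** 2 / err))


def snr(X, Y) -> float:
    X, Y = _pair(X, Y)
    signal = float((Y ** 2).sum())
    if signal == 0:
        raise ValueError("reference image has zero energy")
    noise = float(((X - Y) ** 2).sum())
    if noise == 0:
        return math.inf
    return float(10.0 * np.log10(signal / noise))


def nae(X, Y) -> float:
    X, Y = _pair(X, Y)
    denom = float(X.sum())
    if denom <= 0:
        raise ValueError("sum of processed image must be positive")
    return float(np.abs(X - Y).sum() / denom)


def ncc(X, Y) -> float:
    X, Y = _pair(X, Y)
    denom = float((X ** 2).sum())
    if denom == 0:
        raise ValueError("processed image has zero energy")
    return float((X * Y).sum() / denom)


def ad(X, Y) -> float:
    X, Y = _pair(X, Y)
    return float((X - Y).mean())


def md(X, Y) -> float:
    X, Y = _pair(X, Y)
    return float(np.abs(X - Y).max())


def sc(X, Y) -> float:
    X, Y = _pair(X, Y)
    denom = float((Y ** 2).sum())
    if denom == 0:
        raise ValueError("reference image has zero energy")
    return float((X ** 2).sum() / denom)


def ssim(X, Y, config: QualityConfig = QualityConfig(),
         windowed: bool = False) -> float:
    """Structural similarity; global single-statistic form by default."""
    X, Y = _pair(X, Y)
    if windowed:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(X, Y, data_range=config.peak))
    mx, my = X.mean(), Y.mean()
    vx = ((X - mx) ** 2).mean()
    vy = ((Y - my) ** 2).mean()
    cov = ((X - mx) * (Y - my)).mean()
    c1, c2 = config.ssim_c1, config.ssim_c2
    return float((2 * mx * my + c1) * (2 * cov + c2)
                 / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def all_metrics(X, Y, config: QualityConfig = QualityConfig()) -> dict:
    """All nine metrics of processed X against reference Y."""
    return {
        "mse": mse(X, Y),
        "psnr": psnr(X, Y, config),
        "snr": snr(X, Y),
        "nae": nae(X, Y),
        "ncc": ncc(X, Y),
        "ad": ad(X, Y),
        "md": md(X, Y),
        "sc": sc(X, Y),
        "ssim": ssim(X, Y, config),
    }


@dataclass
class QualityReport:
    """Before/after-fusion quality assessment for one image triple.

    ``before`` compares thermal against visible (the pre-fusion pairing);
    the ``after_*`` entries compare the fused image against each source,
    with ``after_mean`` their per-metric average.
    """

    before: dict[str, float]
    after_thermal: dict[str, float]
    after_visible: dict[str, float]
    after_mean: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"before": self.before,
             "after_vs_thermal": self.after_thermal,
             "after_vs_visible": self.after_visible,
             "after_mean": self.after_mean},
        ).reindex(list(METRIC_NAMES))


def quality_report(fused, thermal, visible,
                   config: QualityConfig = QualityConfig()) -> QualityReport:
    """Table-style quality assessment of one fused image against its two
    co-registered grayscale sources."""
    after_t = all_metrics(fused, thermal, config)
    after_v = all_metrics(fused, visible, config)
    return QualityReport(
        before=all_metrics(thermal, visible, config),
        after_thermal=after_t,
        after_visible=after_v,
        after_mean={k: (after_t[k] + after_v[k]) / 2.0 for k in METRIC_NAMES},
    )


def _aligned_pair(pair):
    """Accept either an aligned (thermal, visible) grayscale tuple or a raw
    ImagePair, which is then grayscaled, resized and registered."""
    if isinstance(pair, (tuple, list)):
        thermal, visible = pair
        return np.asarray(thermal, float), np.asarray(visible, float)
    thermal = np.asarray(pair.thermal, dtype=float)
    visible = to_grayscale(pair.visible)
    visible = resize_to(visible, *thermal.shape)
    _, registered = register_rigid(visible, thermal)
    return thermal, registered


def select_best_rule(pairs, rules=None,
                     config: QualityConfig = QualityConfig(),
                     wavelet: str = "db2", levels: int = 2):
    """Fuse every pair under every rule and pick the best rule.

    Ranks by minimum mean after-fusion MSE (averaged over both references
    and all pairs), breaking ties by maximum mean PSNR, then by canonical
    rule order.  Returns ``(best_rule, table)`` where ``table`` has one row
    per rule with all nine averaged after-fusion metrics.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("select_best_rule needs at least one image pair")
    if rules is None:
        rules = enumerate_rules()
    aligned = [_aligned_pair(p) for p in pairs]
    rows = {}
    for rule in rules:
        acc = {k: 0.0 for k in METRIC_NAMES}
        for thermal, visible in aligned:
            fused = fuse(thermal, visible, rule, wavelet=wavelet,
                         levels=levels)
            rep = quality_report(fused, thermal, visible, config)
            for k in METRIC_NAMES:
                acc[k] += rep.after_mean[k]
        rows[rule.name] = {k: v / len(aligned) for k, v in acc.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    order = {rule.name: i for i, rule in enumerate(rules)}
    best_name = min(table.index,
                    key=lambda r: (table.at[r, "mse"], -table.at[r, "psnr"],
                                   order[r]))
    return FusionRule.from_name(best_name), table
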