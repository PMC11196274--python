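"""Synthetic two-group tongue-imaging study cohort.

Real tongue thermograms from diabetes-screening studies are rarely deposited,
so this module generates a population with the statistical structure the
downstream analysis assumes: 80 normal and 80 type-II-diabetes subjects
(configurable), each with demographic/biochemical values drawn from
group-specific normal distributions, and a paired thermal (320x240, 8-bit)
and visible (390x280, RGB) tongue image per subject.

What the images emulate:

* thermal frame — dark backdrop, elliptical tongue whose central intensity
  maps the subject's tongue temperature linearly over the fixed display
  scale 28.5–36.9 degC onto [0, 255], plus additive Gaussian pixel noise;
* visible frame — a tongue-colored ellipse with a whitish coating patch in
  the upper-to-middle tongue region whose brightness is stronger in the
  diabetic group (the classic thick-coating sign);
* misalignment — the visible content is rigidly displaced relative to the
  thermal frame by a random translation (<= 10 px) and rotation (<= 5 deg),
  recorded in ``ImagePair.true_offset`` so registration can be validated.

The misalignment is injected on the common 240x320 thermal grid *before*
the visible frame is upsampled to its native 280x390 size, so
``true_offset`` is expressed in thermal-grid pixels.

Also provided: the five-technique image augmentation used to inflate small
imaging datasets (shift / horizontal flip / shear / zoom / rotate) and the
stratified 70/15/15 train/validation/test split.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import AffineTransform, warp

from .preprocess import apply_rigid, resize_to

__all__ = [
    "GROUP_PARAMS",
    "TEMP_SCALE",
    "THERMAL_SHAPE",
    "VISIBLE_SHAPE",
    "AUGMENT_TECHNIQUES",
    "SubjectRecord",
    "CohortConfig",
    "ImagePair",
    "generate_cohort",
    "cohort_table",
    "render_tongue_pair",
    "augment",
    "augment_dataset",
    "split_dataset",
    "save_dataset",
]

#: (rows, cols) of the thermal camera frame — 320x240 px width x height.
THERMAL_SHAPE = (240, 320)
#: (rows, cols) of the visible DSLR frame — 390x280 px width x height.
VISIBLE_SHAPE = (280, 390)
#: Fixed thermal display scale in degC; maps linearly onto [0, 255].
TEMP_SCALE = (28.5, 36.9)

#: Per-group (mean, SD) of each physiological variable.  The two groups are
#: age/sex matched; glycaemic variables and tongue temperature separate them
#: (diabetics run ~1.5 degC warmer on the tongue surface).
GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "age": (41.23, 10.82),
        "waist": (91.71, 12.39),
        "hip": (100.11, 11.66),
        "bmi": (25.72, 4.51),
        "sbp": (126.12, 15.38),
        "dbp": (80.10, 9.21),
        "fbg": (87.30, 18.48),
        "ppbg": (114.71, 15.21),
        "hba1c": (5.67, 0.44),
        "tongue_temp": (34.32, 0.42),
    },
    "diabetes": {
        "age": (42.95, 9.63),
        "waist": (93.21, 9.01),
        "hip": (103.18, 8.22),
        "bmi": (27.78, 4.46),
        "sbp": (129.50, 14.31),
        "dbp": (85.85, 10.73),
        "fbg": (148.73, 77.94),
        "ppbg": (228.45, 100.06),
        "hba1c": (8.67, 1.74),
        "tongue_temp": (35.86, 0.80),
    },
}

_FIELDS = ("age", "waist", "hip", "bmi", "sbp", "dbp", "fbg", "ppbg",
           "hba1c", "tongue_temp")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str                       # "normal" | "diabetes"
    sex: str                         # "male" | "female"
    age: float                       # years
    waist: float                     # cm
    hip: float                       # cm
    bmi: float                       # kg m^-2
    sbp: float                       # mmHg
    dbp: float                       # mmHg
    fbg: float                       # mg/dl
    ppbg: float                      # mg/dl
    hba1c: float                     # percent
    tongue_temp: float               # degC


@dataclass
class CohortConfig:
    """Sampling configuration; defaults are the study-population moments."""

    n_per_group: int = 80
    seed: int = 0
    group_params: dict = field(
        default_factory=lambda: copy.deepcopy(GROUP_PARAMS))
    sex_ratio: tuple[int, int] = (1, 2)   # male : female

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for group, params in self.group_params.items():
            for name, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {group}.{name}")
        if min(self.sex_ratio) < 0 or sum(self.sex_ratio) == 0:
            raise ValueError("invalid sex_ratio")


@dataclass
class ImagePair:
    """A subject's thermal + visible frame with the injected misalignment.

    ``true_offset`` is ``(dx, dy, theta_deg)`` on the thermal grid: the rigid
    transform that was applied to the aligned visible content.
    """

    thermal: np.ndarray              # (240, 320) uint8
    visible: np.ndarray              # (280, 390, 3) uint8
    subject_id: str
    true_offset: tuple[float, float, float]

    def __post_init__(self):
        if self.thermal.shape != THERMAL_SHAPE:
            raise ValueError(f"thermal must be {THERMAL_SHAPE}")
        if self.visible.shape != VISIBLE_SHAPE + (3,):
            raise ValueError(f"visible must be {VISIBLE_SHAPE + (3,)}")
        if abs(self.true_offset[2]) > 5.0 + 1e-9:
            raise ValueError("rotation offset exceeds 5 degrees")


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw ``2 * n_per_group`` subjects, each variable an independent
    group-specific normal, clipped below at 0.  Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    prefixes = {"normal": "N", "diabetes": "D"}
    for group in ("normal", "diabetes"):
        params = config.group_params[group]
        n = config.n_per_group
        draws = {name: np.clip(rng.normal(*params[name], size=n), 0.0, None)
                 for name in _FIELDS}
        m_frac = config.sex_ratio[0] / sum(config.sex_ratio)
        n_male = int(round(n * m_frac))
        sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
        rng.shuffle(sexes)
        for i in range(n):
            records.append(SubjectRecord(
                subject_id=f"{prefixes[group]}{i + 1:03d}",
                group=group,
                sex=str(sexes[i]),
                **{name: float(draws[name][i]) for name in _FIELDS},
            ))
    return records


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject, columns named as in :class:`SubjectRecord`."""
    return pd.DataFrame([vars(r) for r in records])


def _ellipse_dist2(shape, center, semi_axes):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / semi_axes[0]) ** 2
            + (((cc - center[1]) / semi_axes[1]) ** 2))


#: Fissure directions (degrees from the vertical midline) of the rendered
#: tongue: the midline sulcus plus lateral cracks.  Shared by both
#: modalities, they anchor the rotational component of registration the way
#: real papillae/fissure texture does.
_CRACK_ANGLES = (0.0, -55.0, 35.0, 75.0)


def _crack_weights(shape, center, semi_axes):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    u = (rr - center[0]) / semi_axes[0]
    v = (cc - center[1]) / semi_axes[1]
    radius = np.sqrt(u * u + v * v)
    w = np.zeros(shape)
    for ang in _CRACK_ANGLES:
        a = np.deg2rad(ang)
        # signed distance (px) to the ray from the center at angle `ang`
        d = (rr - center[0]) * np.sin(a) - (cc - center[1]) * np.cos(a)
        along = (rr - center[0]) * np.cos(a) + (cc - center[1]) * np.sin(a)
        seg = np.exp(-(d / 1.6) ** 2) * (along > 0.12 * semi_axes[0])
        w = np.maximum(w, seg)
    # confined to an annulus outside the central 50x50 ROI (radius ~0.46)
    # so fissures never perturb the ROI's temperature/coating statistics
    inner = np.clip((radius - 0.50) / 0.06, 0.0, 1.0)
    outer = np.clip(1.0 - (radius - 0.82) / 0.12, 0.0, 1.0)
    return w * inner * outer


def render_tongue_pair(record: SubjectRecord, seed: int,
                       noise_sd: float = 3.0, max_shift: float = 10.0,
                       max_rot: float = 5.0) -> ImagePair:
    """Render a subject's thermal/visible frame pair.

    The thermal tongue interior is flat (at the temperature-mapped intensity)
    out to 55% of the ellipse radius — well beyond the central 50x50 ROI —
    then fades toward the rim, so the ROI mean tracks ``tongue_temp``
    linearly.  The visible coating patch sits in the upper-to-middle tongue
    region and overlaps the top of the ROI; its amplitude is drawn per
    subject around a group-dependent level (diabetes brighter).
    """
    rng = np.random.default_rng(seed)
    H, W = THERMAL_SHAPE
    center = (120.0, 160.0)
    semi = (85.0, 70.0)
    d2 = _ellipse_dist2(THERMAL_SHAPE, center, semi)
    inside = d2 <= 1.0
    r = np.sqrt(d2)
    profile = 1.0 - 0.3 * np.clip((r - 0.55) / 0.45, 0.0, 1.0)

    cracks = _crack_weights(THERMAL_SHAPE, center, semi)
    # shared papillae micro-texture: a smooth zero-mean random field drawn on
    # the aligned grid, expressed (with different gains) in both modalities —
    # the correlated fine structure real registration locks on to
    texture = ndimage.gaussian_filter(
        rng.standard_normal(THERMAL_SHAPE), sigma=2.5)
    texture /= texture.std()

    # --- thermal frame ---------------------------------------------------
    lo, hi = TEMP_SCALE
    t = float(np.clip(record.tongue_temp, lo, hi))
    t_int = 255.0 * (t - lo) / (hi - lo)
    thermal = np.where(inside, t_int * profile, 8.0)
    thermal -= 0.08 * t_int * cracks * inside  # fissures run slightly cooler
    thermal += 6.0 * texture * inside
    thermal = thermal + rng.normal(0.0, noise_sd, thermal.shape)
    thermal = np.clip(thermal, 0, 255)

    # --- visible scene on the (aligned) thermal grid ---------------------
    base = np.array([178.0, 96.0, 106.0]) + rng.normal(0.0, 5.0, 3)
    backdrop = np.array([20.0, 12.0, 14.0])
    scene = np.empty(THERMAL_SHAPE + (3,))
    for ch in range(3):
        scene[..., ch] = np.where(inside, base[ch] * profile, backdrop[ch])
    # whitish coating, upper-to-middle tongue region
    coat_level = 38.0 if record.group == "diabetes" else 22.0
    amp = max(coat_level + rng.normal(0.0, 8.0), 0.0)
    coat_w = np.clip(1.0 - _ellipse_dist2(THERMAL_SHAPE, (95.0, 160.0),
                                          (38.0, 46.0)), 0.0, 1.0)
    scene += (amp * coat_w * inside)[..., None]
    scene -= (45.0 * cracks * inside)[..., None]  # fissures read darker
    scene += (12.0 * texture * inside)[..., None]
    scene = np.clip(scene, 0, 255)

    # --- misalignment + native visible resolution ------------------------
    theta = float(rng.uniform(-max_rot, max_rot))
    dx, dy = (float(v) for v in rng.uniform(-max_shift, max_shift, 2))
    moved = np.dstack([
        apply_rigid(scene[..., ch], dx, dy, theta, cval=backdrop[ch])
        for ch in range(3)
    ])
    visible = resize_to(moved, *VISIBLE_SHAPE)
    visible = visible + rng.normal(0.0, noise_sd, visible.shape)
    visible = np.clip(visible, 0, 255)

    return ImagePair(
        thermal=np.round(thermal).astype(np.uint8),
        visible=np.round(visible).astype(np.uint8),
        subject_id=record.subject_id,
        true_offset=(dx, dy, theta),
    )


AUGMENT_TECHNIQUES = ("shift", "hflip", "shear", "zoom", "rotate")


def _centered_warp(image, transform: AffineTransform):
    """Warp with a transform applied about the image center, keeping dims."""
    center = (np.array(image.shape[:2][::-1]) - 1) / 2.0  # (x, y)
    shift = AffineTransform(translation=-center)
    full = shift + transform + AffineTransform(translation=center)
    return warp(image, full.inverse, order=1, preserve_range=True,
                mode="constant", cval=0.0)


def augment(image, technique: str, seed: int = 0, *, shift=None, angle=None,
            shear=None, zoom=None) -> np.ndarray:
    """Apply one of the five dataset-augmentation transforms.

    Parameters left as ``None`` are drawn from ``seed`` (shift up to 10% of
    each dimension, rotation up to +/-15 deg, shear up to +/-10 deg, zoom in
    0.9–1.1).  Output has the input's dimensions; ``hflip`` is exactly
    involutive, and identity parameters (zero shift/angle/shear, zoom 1)
    return the image unchanged.
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    if technique == "hflip":
        return image[:, ::-1].copy()
    if technique == "shift":
        if shift is None:
            shift = (rng.uniform(-0.1, 0.1) * image.shape[1],
                     rng.uniform(-0.1, 0.1) * image.shape[0])
        if shift == (0, 0):
            return image.copy()
        tf = AffineTransform(translation=shift)  # (dx, dy)
    elif technique == "rotate":
        if angle is None:
            angle = rng.uniform(-15.0, 15.0)
        if angle == 0:
            return image.copy()
        tf = AffineTransform(rotation=np.deg2rad(angle))
    elif technique == "shear":
        if shear is None:
            shear = rng.uniform(-10.0, 10.0)
        if shear == 0:
            return image.copy()
        tf = AffineTransform(shear=np.deg2rad(shear))
    elif technique == "zoom":
        if zoom is None:
            zoom = rng.uniform(0.9, 1.1)
        if zoom == 1:
            return image.copy()
        tf = AffineTransform(scale=(zoom, zoom))
    else:
        raise ValueError(
            f"unknown technique {technique!r}; expected one of "
            f"{AUGMENT_TECHNIQUES}")
    return _centered_warp(image, tf)


def augment_dataset(images, techniques=AUGMENT_TECHNIQUES, seed: int = 0):
    """Originals followed by one augmented copy per (image, technique).

    With the five standard techniques, N source images become 6N total
    (N originals + 5N augmented).
    """
    out = [np.asarray(im, dtype=float).copy() for im in images]
    for j, technique in enumerate(techniques):
        for i, im in enumerate(images):
            out.append(augment(im, technique, seed=seed * 100003 + j * 1009 + i))
    return out


def split_dataset(items, fractions=(0.70, 0.15, 0.15), seed: int = 0,
                  labels=None):
    """Disjoint, exhaustive train/validation/test split.

    Validation and test sizes are ``floor(fraction * N)`` (per stratum when
    ``labels`` is given), with the remainder assigned to training — so 160
    stratified items at (0.70, 0.15, 0.15) split 112/24/24 and 960 split
    672/144/144.  Deterministic for a fixed seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if len(fractions) != 3:
        raise ValueError("expected (train, val, test) fractions")
    items = list(items)
    rng = np.random.default_rng(seed)
    if labels is None:
        strata = {None: np.arange(len(items))}
    else:
        labels = np.asarray(labels)
        if len(labels) != len(items):
            raise ValueError("labels length mismatch")
        strata = {lab: np.flatnonzero(labels == lab)
                  for lab in pd.unique(labels)}
    train_idx, val_idx, test_idx = [], [], []
    for idx in strata.values():
        perm = idx[rng.permutation(len(idx))]
        n = len(perm)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:n_train + n_val])
        test_idx.extend(perm[n_train + n_val:])
    return ([items[i] for i in sorted(train_idx)],
            [items[i] for i in sorted(val_idx)],
            [items[i] for i in sorted(test_idx)])


def save_dataset(records, outdir, seed: int = 0, **render_kwargs):
    """Write the cohort CSV plus per-subject thermal/visible PNGs.

    Returns the list of rendered :class:`ImagePair` objects.  Per-subject
    render seeds are derived from ``seed`` and the subject index.
    """
    import pathlib

    import imageio.v3 as iio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_table(records).to_csv(outdir / "cohort.csv", index=False)
    pairs = []
    for i, rec in enumerate(records):
        pair = render_tongue_pair(rec, seed=seed * 65537 + i, **render_kwargs)
        iio.imwrite(outdir / f"{rec.subject_id}_thermal.png", pair.thermal)
        iio.imwrite(outdir / f"{rec.subject_id}_visible.png", pair.visible)
        pairs.append(pair)
    return pairs
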