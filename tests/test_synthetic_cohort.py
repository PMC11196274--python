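"""Cohort generation, image rendering, augmentation and dataset splitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tonguefusion as tf
from tonguefusion.synthetic_cohort import _FIELDS


class TestGenerateCohort:
    def test_counts_and_groups(self):
        recs = tf.generate_cohort(tf.CohortConfig(n_per_group=80, seed=1))
        assert len(recs) == 160
        assert sum(r.group == "normal" for r in recs) == 80
        assert sum(r.group == "diabetes" for r in recs) == 80

    def test_reproducible_and_seed_sensitive(self):
        a = tf.generate_cohort(tf.CohortConfig(n_per_group=5, seed=3))
        b = tf.generate_cohort(tf.CohortConfig(n_per_group=5, seed=3))
        c = tf.generate_cohort(tf.CohortConfig(n_per_group=5, seed=4))
        assert a == b
        assert a != c

    def test_zero_variance_returns_group_means(self):
        cfg = tf.CohortConfig(n_per_group=1, seed=0)
        for group in cfg.group_params:
            for name, (mu, _) in cfg.group_params[group].items():
                cfg.group_params[group][name] = (mu, 0.0)
        recs = tf.generate_cohort(cfg)
        for rec in recs:
            for name in _FIELDS:
                assert getattr(rec, name) == pytest.approx(
                    cfg.group_params[rec.group][name][0])

    def test_temperature_difference_recovers_printed_effect(self):
        # group-mean separation of 35.86 - 34.32 = 1.54 degC at n=2000/group
        recs = tf.generate_cohort(tf.CohortConfig(n_per_group=2000, seed=7))
        temps = {g: np.mean([r.tongue_temp for r in recs if r.group == g])
                 for g in ("normal", "diabetes")}
        assert abs(temps["diabetes"] - temps["normal"] - 1.54) < 0.05

    def test_all_values_positive_finite(self):
        recs = tf.generate_cohort(tf.CohortConfig(n_per_group=50, seed=9))
        for rec in recs:
            for name in _FIELDS:
                v = getattr(rec, name)
                assert np.isfinite(v) and v >= 0

    def test_sex_ratio(self):
        recs = tf.generate_cohort(tf.CohortConfig(n_per_group=60, seed=2))
        for g in ("normal", "diabetes"):
            males = sum(r.sex == "male" for r in recs if r.group == g)
            assert males == 20  # 1:2 male:female

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tf.generate_cohort(tf.CohortConfig(n_per_group=0))
        bad = tf.CohortConfig()
        bad.group_params["normal"]["age"] = (40.0, -1.0)
        with pytest.raises(ValueError):
            tf.generate_cohort(bad)


class TestRenderTonguePair:
    def test_frame_geometry(self, rendered_pair):
        assert rendered_pair.thermal.shape == (240, 320)
        assert rendered_pair.visible.shape == (280, 390, 3)
        dx, dy, theta = rendered_pair.true_offset
        assert abs(theta) <= 5.0
        assert abs(dx) <= 10.0 and abs(dy) <= 10.0

    def test_deterministic_per_seed(self, small_cohort):
        a = tf.render_tongue_pair(small_cohort[0], seed=11)
        b = tf.render_tongue_pair(small_cohort[0], seed=11)
        c = tf.render_tongue_pair(small_cohort[0], seed=12)
        assert np.array_equal(a.thermal, b.thermal)
        assert np.array_equal(a.visible, b.visible)
        assert not np.array_equal(a.thermal, c.thermal)

    @pytest.mark.parametrize("temp,expected", [(36.9, 255.0), (28.5, 0.0)])
    def test_roi_intensity_at_scale_extremes(self, small_cohort, temp,
                                             expected):
        rec = dataclasses.replace(small_cohort[0], tongue_temp=temp)
        pair = tf.render_tongue_pair(rec, seed=5)
        roi = tf.extract_central_roi(np.asarray(pair.thermal, float))
        # clipping of the additive pixel/texture noise at the intensity rail
        # shifts the mean a few units inward of the exact endpoint
        assert roi.mean() == pytest.approx(expected, abs=6.0)

    def test_roi_mean_monotone_in_temperature(self, small_cohort):
        grid = np.linspace(29.0, 36.5, 8)
        means = []
        for t in grid:
            rec = dataclasses.replace(small_cohort[0], tongue_temp=float(t))
            pair = tf.render_tongue_pair(rec, seed=31)
            roi = tf.extract_central_roi(np.asarray(pair.thermal, float))
            means.append(roi.mean())
        assert np.all(np.diff(means) > 0)

    def test_diabetic_coating_brightens_visible_roi(self):
        recs = tf.generate_cohort(tf.CohortConfig(n_per_group=4, seed=42))
        means = {"normal": [], "diabetes": []}
        for i, rec in enumerate(recs):
            pair = tf.render_tongue_pair(rec, seed=900 + i)
            gray = tf.resize_to(tf.to_grayscale(pair.visible), 240, 320)
            means[rec.group].append(tf.extract_central_roi(gray).mean())
        assert np.mean(means["diabetes"]) > np.mean(means["normal"])


class TestAugment:
    def test_hflip_is_involutive(self, random_image):
        flipped = tf.augment(random_image, "hflip")
        assert not np.array_equal(flipped, random_image)
        assert np.array_equal(tf.augment(flipped, "hflip"), random_image)

    def test_identity_parameters_leave_image_unchanged(self, random_image):
        assert np.array_equal(
            tf.augment(random_image, "shift", shift=(0, 0)), random_image)
        assert np.array_equal(
            tf.augment(random_image, "rotate", angle=0), random_image)
        assert np.array_equal(
            tf.augment(random_image, "zoom", zoom=1), random_image)

    @pytest.mark.parametrize("technique", tf.AUGMENT_TECHNIQUES)
    def test_output_dimensions_preserved(self, random_image, technique):
        out = tf.augment(random_image, technique, seed=3)
        assert out.shape == random_image.shape

    def test_unknown_technique_rejected(self, random_image):
        with pytest.raises(ValueError, match="unknown technique"):
            tf.augment(random_image, "posterize")

    def test_dataset_accounting_160_to_960(self, rng):
        images = [rng.uniform(0, 255, (16, 16)) for _ in range(160)]
        out = tf.augment_dataset(images, seed=1)
        assert len(out) == 960                       # 160 + 160*5
        assert len(out) / len(images) == 6.0


class TestSplitDataset:
    @pytest.mark.parametrize("n,expected", [
        (160, (112, 24, 24)),     # the 160-subject feature-table split
        (960, (672, 144, 144)),   # the augmented-image split
        (10, (8, 1, 1)),          # floor rule, remainder to training
    ])
    def test_printed_split_sizes(self, n, expected):
        train, val, test = tf.split_dataset(list(range(n)), seed=5)
        assert (len(train), len(val), len(test)) == expected

    def test_stratified_split_balances_groups(self):
        labels = np.array(["normal"] * 80 + ["diabetes"] * 80)
        train, val, test = tf.split_dataset(
            list(range(160)), seed=1, labels=labels)
        assert (len(train), len(val), len(test)) == (112, 24, 24)
        for part in (train, val, test):
            groups = labels[np.asarray(part)]
            assert (groups == "normal").sum() == (groups == "diabetes").sum()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(min_value=3, max_value=500),
           seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_disjoint_and_exhaustive(self, n, seed):
        items = list(range(n))
        parts = tf.split_dataset(items, seed=seed)
        flat = [i for part in parts for i in part]
        assert sorted(flat) == items
        assert sum(len(p) for p in parts) == n

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            tf.split_dataset([1, 2, 3], fractions=(0.5, 0.3, 0.3))

    def test_deterministic(self):
        a = tf.split_dataset(list(range(50)), seed=3)
        b = tf.split_dataset(list(range(50)), seed=3)
        assert a == b


def test_save_dataset_roundtrip(tmp_path, small_cohort):
    import imageio.v3 as iio
    import pandas as pd

    pairs = tf.save_dataset(small_cohort, tmp_path, seed=1)
    table = pd.read_csv(tmp_path / "cohort.csv")
    assert len(table) == len(small_cohort)
    back = iio.imread(tmp_path / f"{small_cohort[0].subject_id}_thermal.png")
    assert np.array_equal(back, pairs[0].thermal)
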