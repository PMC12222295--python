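"""Pixel classification, small-object suppression and area fractions."""

import numpy as np
import pytest
from scipy import ndimage

from gliascore import (
    ScribbleSet,
    SegmentationMask,
    area_fraction,
    extract_features,
    filter_small_objects,
    segment,
    train_pixel_classifier,
)
from gliascore.io_projection import Projection
from gliascore.pipeline import segment_scene


def _projection(raster, label="astrocyte"):
    return Projection(channels={label: np.asarray(raster, dtype=np.uint16)})


def _separable_case():
    """Two-intensity image: a bright square object on dark background."""
    img = np.full((32, 32), 1000, dtype=np.uint16)
    img[8:24, 8:24] = 50000
    truth = img == 50000
    entries = [(r, c, "object") for r, c in [(10, 10), (12, 15), (20, 20), (15, 12), (22, 10)]]
    entries += [(r, c, "background") for r, c in [(0, 0), (2, 30), (30, 2), (29, 29), (4, 4)]]
    return _projection(img), truth, ScribbleSet(entries=entries, channel_label="astrocyte")


class TestFeatures:
    def test_constant_image_gives_identical_feature_vectors(self):
        feats = extract_features(_projection(np.full((16, 16), 777)), "astrocyte")
        assert np.allclose(feats, feats[0])

    def test_gradient_feature_peaks_on_step_edge(self):
        img = np.zeros((16, 16), dtype=np.uint16)
        img[:, 8:] = 60000
        feats = extract_features(_projection(img), "astrocyte")
        grad = feats[:, 4].reshape(16, 16)
        peak_cols = np.argmax(grad, axis=1)
        assert np.all(np.isin(peak_cols, (7, 8)))

    def test_smoothing_at_vanishing_scale_converges_to_raw(self, rng):
        img = rng.integers(0, 65535, size=(24, 24)).astype(np.uint16)
        smoothed = ndimage.gaussian_filter(img.astype(np.float32), sigma=1e-3)
        np.testing.assert_allclose(smoothed, img, atol=1e-2)

    def test_absent_channel_raises(self):
        with pytest.raises(KeyError):
            extract_features(_projection(np.zeros((4, 4))), "nucleus")


class TestTraining:
    def test_separable_case_training_accuracy_is_one(self):
        proj, _, scribbles = _separable_case()
        feats = extract_features(proj, "astrocyte")
        model = train_pixel_classifier(feats, scribbles, proj.shape, seed=0)
        assert model.training_accuracy == 1.0

    def test_single_class_scribbles_rejected(self):
        proj, _, _ = _separable_case()
        feats = extract_features(proj, "astrocyte")
        scribbles = ScribbleSet(
            entries=[(1, 1, "background"), (2, 2, "background")], channel_label="astrocyte"
        )
        with pytest.raises(ValueError, match="both"):
            train_pixel_classifier(feats, scribbles, proj.shape)

    def test_overlapping_intensities_match_centroid_oracle(self, rng):
        # object and background intensity distributions overlap heavily; on
        # held-out pixels the trained classifier should perform like a
        # nearest-class-centroid rule on raw intensity (the Bayes-optimal
        # shape for two equal-variance normals), to within 0.05
        rows, cols = 60, 40
        n = rows * cols // 2
        labels = np.zeros(rows * cols, dtype=bool)
        labels[:n] = True
        obj_vals = rng.normal(30000, 6000, n)
        bg_vals = rng.normal(22000, 6000, n)
        vals = np.clip(np.concatenate([obj_vals, bg_vals]), 0, 65535)
        order = rng.permutation(rows * cols)
        vals, labels = vals[order], labels[order]
        raster = vals.reshape(rows, cols).astype(np.uint16)
        proj = _projection(raster)

        train_idx = np.arange(0, rows * cols, 4)
        test_idx = np.setdiff1d(np.arange(rows * cols), train_idx)
        entries = [
            (i // cols, i % cols, "object" if labels[i] else "background")
            for i in train_idx
        ]
        scribbles = ScribbleSet(entries=entries, channel_label="astrocyte")
        feats = extract_features(proj, "astrocyte")
        model = train_pixel_classifier(feats, scribbles, proj.shape, seed=0)
        model_acc = (model.predict(feats[test_idx]) == labels[test_idx]).mean()

        v = raster.ravel().astype(float)
        c_obj = v[train_idx][labels[train_idx]].mean()
        c_bg = v[train_idx][~labels[train_idx]].mean()
        centroid_pred = np.abs(v[test_idx] - c_obj) < np.abs(v[test_idx] - c_bg)
        centroid_acc = (centroid_pred == labels[test_idx]).mean()
        assert abs(model_acc - centroid_acc) <= 0.05


class TestSegment:
    def test_separable_training_image_segmented_exactly(self):
        proj, truth, scribbles = _separable_case()
        feats = extract_features(proj, "astrocyte")
        model = train_pixel_classifier(feats, scribbles, proj.shape, seed=0)
        mask = segment(proj, model)
        np.testing.assert_array_equal(mask.mask, truth)
        assert mask.min_object_size_px == 0

    def test_all_background_image_yields_empty_mask(self):
        proj, _, scribbles = _separable_case()
        feats = extract_features(proj, "astrocyte")
        model = train_pixel_classifier(feats, scribbles, proj.shape, seed=0)
        flat = _projection(np.full((32, 32), 1000))
        assert not segment(flat, model).mask.any()

    def test_recipe_mismatch_rejected(self):
        proj, _, scribbles = _separable_case()
        feats = extract_features(proj, "astrocyte")
        model = train_pixel_classifier(feats, scribbles, proj.shape, seed=0)
        model.recipe = "other-recipe-v0"
        with pytest.raises(ValueError, match="recipe"):
            segment(proj, model)

    def test_synthetic_scene_pixel_agreement(self, demo_scene):
        masks = segment_scene(demo_scene, channels=("microglia",), seed=0)
        truth = demo_scene.truth.object_rasters["microglia"]
        agreement = (masks["microglia"].mask == truth).mean()
        assert agreement >= 0.95

    def test_retraining_same_seed_reproduces_identical_mask(self, demo_scene):
        a = segment_scene(demo_scene, channels=("nucleus",), seed=11)["nucleus"]
        b = segment_scene(demo_scene, channels=("nucleus",), seed=11)["nucleus"]
        np.testing.assert_array_equal(a.mask, b.mask)


class TestFilterSmallObjects:
    def _mask_with_sizes(self, sizes):
        """Well-separated horizontal runs, one per requested size."""
        width = max(sizes) + 2
        mask = np.zeros((2 * len(sizes) + 1, width), dtype=bool)
        for i, s in enumerate(sizes):
            mask[2 * i + 1, 1 : 1 + s] = True
        return SegmentationMask(mask, "microglia")

    def test_strictly_below_threshold_removed_at_removed_kept(self):
        mask = self._mask_with_sizes([23, 24, 25])
        out = filter_small_objects(mask, min_size=24)
        labels, n = ndimage.label(out.mask, structure=np.ones((3, 3), bool))
        sizes = sorted(np.bincount(labels.ravel())[1:])
        assert sizes == [24, 25]

    def test_min_size_zero_is_identity(self):
        mask = self._mask_with_sizes([1, 5, 9])
        out = filter_small_objects(mask, min_size=0)
        np.testing.assert_array_equal(out.mask, mask.mask)

    def test_negative_min_size_rejected(self):
        with pytest.raises(ValueError):
            filter_small_objects(self._mask_with_sizes([3]), min_size=-1)

    def test_idempotent_and_all_survivors_at_least_min_size(self, rng):
        mask = SegmentationMask(rng.random((64, 64)) > 0.6, "microglia")
        once = filter_small_objects(mask, min_size=24)
        twice = filter_small_objects(once, min_size=24)
        np.testing.assert_array_equal(once.mask, twice.mask)
        labels, n = ndimage.label(once.mask, structure=np.ones((3, 3), bool))
        if n:
            assert np.bincount(labels.ravel())[1:].min() >= 24

    def test_diagonal_pixels_count_as_one_group(self):
        mask = np.zeros((30, 30), dtype=bool)
        for i in range(24):  # diagonal chain: 24 px in 8-connectivity
            mask[i, i] = True
        out = filter_small_objects(SegmentationMask(mask, "microglia"), min_size=24)
        assert out.mask.sum() == 24


class TestAreaFraction:
    @pytest.mark.parametrize(
        "mask,expected",
        [
            (np.zeros((10, 10), dtype=bool), 0.0),
            (np.ones((10, 10), dtype=bool), 100.0),
            (np.kron([[1, 0], [0, 1]], np.ones((5, 5))).astype(bool), 50.0),
        ],
    )
    def test_reference_fractions(self, mask, expected):
        assert area_fraction(SegmentationMask(mask, "microglia")) == expected

    def test_monotone_under_mask_union(self, rng):
        a = rng.random((32, 32)) > 0.7
        b = a | (rng.random((32, 32)) > 0.8)
        assert area_fraction(
            SegmentationMask(b, "microglia")
        ) >= area_fraction(SegmentationMask(a, "microglia"))

    def test_zero_area_image_rejected(self):
        with pytest.raises(ValueError):
            area_fraction(SegmentationMask(np.zeros((0, 0), dtype=bool), "microglia"))

    def test_planted_area_fraction_recovered_within_two_points(self, demo_scene):
        masks = segment_scene(demo_scene, channels=("microglia",), seed=0)
        measured = area_fraction(masks["microglia"])
        truth = demo_scene.truth.object_rasters["microglia"]
        planted = 100.0 * truth.sum() / truth.size
        assert abs(measured - planted) <= 2.0
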