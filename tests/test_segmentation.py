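import math

import numpy as np
import pytest

from braincad.enhancement import tssr_enhance
from braincad.evaluation import confusion_from_masks, metrics
from braincad.image_io import IntensityHistogram, to_histogram
from braincad.segmentation import (
    MorphParams,
    apply_threshold,
    count_components,
    kapur_entropy,
    max_entropy_threshold,
    morphological_cleanup,
    segment,
)


def hist_from_probs(probs: dict[int, float], total: int = 1000) -> IntensityHistogram:
    counts = np.zeros(256, dtype=np.int64)
    for level, p in probs.items():
        counts[level] = round(p * total)
    return IntensityHistogram(counts=counts, probabilities=counts / counts.sum())


def exhaustive_kapur(hist: IntensityHistogram) -> tuple[int, float]:
    """Independent oracle: direct loop evaluation of the two side entropies
    at every split level, smallest argmax."""
    p = hist.probabilities
    best_t, best_h = None, -1.0
    for t in range(256):
        p1 = sum(p[: t + 1])
        p2 = sum(p[t + 1 :])
        if p1 <= 0 or p2 <= 0:
            continue
        h = 0.0
        for k in range(t + 1):
            if p[k] > 0:
                h -= (p[k] / p1) * math.log(p[k] / p1)
        for k in range(t + 1, 256):
            if p[k] > 0:
                h -= (p[k] / p2) * math.log(p[k] / p2)
        if h > best_h + 1e-12:
            best_t, best_h = t, h
    return best_t, best_h


EIGHT_PIXEL = hist_from_probs({0: 0.375, 100: 0.125, 200: 0.5}, total=8)


class TestKapurEntropy:
    def test_two_delta_histogram_zero_entropy(self):
        h = hist_from_probs({50: 0.5, 200: 0.5})
        assert kapur_entropy(h, 100) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_split_at_100(self):
        # foreground {0.75, 0.25}: -(0.75 ln 0.75 + 0.25 ln 0.25) = 0.5623
        h = kapur_entropy(EIGHT_PIXEL, 100)
        assert h == pytest.approx(0.5623, abs=5e-5)

    def test_hand_worked_split_at_50(self):
        # background {0.2, 0.8} entropy = 0.5004
        h = kapur_entropy(EIGHT_PIXEL, 50)
        assert h == pytest.approx(0.5004, abs=5e-5)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="empty side"):
            kapur_entropy(EIGHT_PIXEL, 250)


class TestMaxEntropyThreshold:
    def test_eight_pixel_example(self):
        res = max_entropy_threshold(EIGHT_PIXEL)
        assert res.t_opt == 100
        assert res.h_max == pytest.approx(0.5623, abs=5e-5)
        assert res.t_norm == pytest.approx(res.h_max / 255)

    def test_tie_broken_to_smallest_level(self):
        res = max_entropy_threshold(hist_from_probs({50: 0.5, 200: 0.5}))
        assert res.t_opt == 50  # every valid split ties at H=0

    def test_uniform_histogram_splits_at_midpoint(self):
        counts = np.ones(256, dtype=np.int64)
        h = IntensityHistogram(counts=counts, probabilities=counts / 256)
        assert max_entropy_threshold(h).t_opt == 127

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_levels = rng.integers(2, 40)
            levels = rng.choice(256, size=n_levels, replace=False)
            counts = np.zeros(256, dtype=np.int64)
            counts[levels] = rng.integers(1, 1000, size=n_levels)
            h = IntensityHistogram(counts=counts, probabilities=counts / counts.sum())
            res = max_entropy_threshold(h)
            t_ref, h_ref = exhaustive_kapur(h)
            assert res.t_opt == t_ref
            assert res.h_max == pytest.approx(h_ref, abs=1e-9)

    def test_scaling_counts_leaves_threshold_unchanged(self, rng):
        counts = np.zeros(256, dtype=np.int64)
        counts[rng.choice(256, 20, replace=False)] = rng.integers(1, 50, 20)
        h1 = IntensityHistogram(counts=counts, probabilities=counts / counts.sum())
        h2 = IntensityHistogram(
            counts=counts * 7, probabilities=(counts * 7) / (counts.sum() * 7)
        )
        assert max_entropy_threshold(h1).t_opt == max_entropy_threshold(h2).t_opt

    def test_entropy_curve_nonnegative_and_additive(self):
        res = max_entropy_threshold(EIGHT_PIXEL)
        valid = res.entropy_curve[~np.isnan(res.entropy_curve)]
        assert (valid >= -1e-12).all()

    def test_single_level_histogram_rejected(self):
        with pytest.raises(ValueError, match="single occupied level"):
            max_entropy_threshold(hist_from_probs({7: 1.0}))


class TestApplyThreshold:
    def test_strictly_greater(self):
        assert np.array_equal(
            apply_threshold(np.array([[0, 255]], dtype=np.uint8), 100),
            np.array([[0, 1]], dtype=np.uint8),
        )

    def test_threshold_255_empty_mask(self, rng):
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        assert apply_threshold(img, 255).sum() == 0

    def test_eight_pixel_example_selects_200s(self):
        img = np.array([0, 0, 0, 100, 200, 200, 200, 200], dtype=np.uint8).reshape(2, 4)
        t = max_entropy_threshold(to_histogram(img)).t_opt
        assert np.array_equal(apply_threshold(img, t).ravel(), [0, 0, 0, 0, 1, 1, 1, 1])


class TestMorphologicalCleanup:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[32, 32] = 1
        assert morphological_cleanup(mask, MorphParams(disk_radius=8)).sum() == 0

    def test_large_disk_preserved_square_keeps_interior(self):
        from skimage.morphology import disk as disk_fp

        # opening by a disk is (near-)identity on a larger disk; digital
        # disk rasterization can nibble a few boundary pixels
        mask = np.zeros((100, 100), dtype=np.uint8)
        mask[20:81, 20:81] = disk_fp(30)
        out = morphological_cleanup(mask, MorphParams(disk_radius=10))
        assert not (out & ~mask).any()
        assert mask.sum() - out.sum() <= 0.01 * mask.sum()

        # a square keeps everything except its rounded corners
        square = np.zeros((100, 100), dtype=np.uint8)
        square[20:80, 20:80] = 1
        out = morphological_cleanup(square, MorphParams(disk_radius=10))
        assert (out[30:70, 30:70] == 1).all()
        assert square.sum() - out.sum() < 4 * 10 * 10  # at most the corner caps

    def test_idempotent(self, rng):
        mask = (rng.random((128, 128)) < 0.4).astype(np.uint8)
        once = morphological_cleanup(mask)
        twice = morphological_cleanup(once)
        assert np.array_equal(once, twice)

    def test_never_adds_foreground(self, rng):
        mask = (rng.random((128, 128)) < 0.5).astype(np.uint8)
        out = morphological_cleanup(mask)
        assert not (out & ~mask).any()

    def test_disk_radius_range_enforced(self):
        with pytest.raises(ValueError):
            MorphParams(disk_radius=5)


class TestSegmentPipeline:
    def test_tumor_phantom_dsc(self, tumor_phantom):
        image, truth, _ = tumor_phantom
        mask, result = segment(tssr_enhance(image))
        dsc = metrics(confusion_from_masks(mask, truth)).DSC
        assert dsc >= 85.0
        assert 0 <= result.t_opt <= 254

    def test_two_tumors_two_components(self):
        from braincad import PhantomSpec, generate_phantom

        image, truth, _ = generate_phantom(PhantomSpec(n_tumors=2, seed=3))
        mask, _ = segment(tssr_enhance(image))
        assert count_components(mask) == 2

    def test_constant_image_degenerate(self):
        with pytest.raises(ValueError):
            segment(np.full((256, 256), 9, dtype=np.uint8))
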