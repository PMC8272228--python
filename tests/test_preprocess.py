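import numpy as np
import pytest

from thermarm.errors import ConfigError, DegenerateHistogramError, SegmentationError
from thermarm.preprocess import (
    ArmMask,
    align_frame,
    crop_roi,
    otsu_threshold,
    segment_arm,
    smooth,
)
from thermarm.thermal_io import ThermalFrame


def otsu_bruteforce(values: np.ndarray, nbins: int = 256):
    """Exhaustive search over all candidate thresholds of a 256-bin histogram.

    Returns (threshold, max between-class variance); the threshold is the
    center of the last bin of the lower class, and the variance is the
    weighted squared distance of the two class means.
    """
    hist, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best_thr, best_var = None, -1.0
    for i in range(1, nbins):
        w0, w1 = hist[:i].sum(), hist[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i] * centers[:i]).sum() / w0
        m1 = (hist[i:] * centers[i:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[i - 1]
    return best_thr, best_var


def variance_at(values: np.ndarray, thr: float, nbins: int = 256) -> float:
    """Between-class variance (histogram objective) of the split at ``thr``."""
    hist, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    lower = centers <= thr
    w0, w1 = hist[lower].sum(), hist[~lower].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    m0 = (hist[lower] * centers[lower]).sum() / w0
    m1 = (hist[~lower] * centers[~lower]).sum() / w1
    total = hist.sum()
    return (w0 / total) * (w1 / total) * (m0 - m1) ** 2


class TestAlign:
    def test_left_arm_unchanged(self, rng):
        f = ThermalFrame(rng.uniform(25, 35, (6, 8)))
        out = align_frame(f, "left")
        np.testing.assert_array_equal(out.temperatures, f.temperatures)

    def test_right_arm_mirrored(self, rng):
        f = ThermalFrame(rng.uniform(25, 35, (6, 8)))
        out = align_frame(f, "right")
        np.testing.assert_array_equal(out.temperatures, f.temperatures[:, ::-1])

    def test_mirror_is_involution(self, rng):
        f = ThermalFrame(rng.uniform(25, 35, (6, 8)))
        twice = align_frame(align_frame(f, "right"), "right")
        np.testing.assert_array_equal(twice.temperatures, f.temperatures)

    def test_invalid_side(self, rng):
        with pytest.raises(ConfigError):
            align_frame(ThermalFrame(np.full((2, 2), 30.0)), "both")


class TestSmooth:
    def test_constant_frame_unchanged(self):
        f = ThermalFrame(np.full((10, 10), 31.5))
        np.testing.assert_allclose(smooth(f, 3, 3).temperatures, 31.5)

    def test_interior_impulse_spreads_to_kernel(self):
        arr = np.zeros((9, 9))
        arr[4, 4] = 9.0
        out = smooth(ThermalFrame(arr), 3, 3).temperatures
        np.testing.assert_allclose(out[3:6, 3:6], 1.0)
        assert out[2, 4] == 0.0

    def test_identity_kernel(self, rng):
        f = ThermalFrame(rng.uniform(25, 35, (5, 5)))
        np.testing.assert_array_equal(smooth(f, 1, 1).temperatures, f.temperatures)

    def test_mean_filter_is_a_contraction(self, rng):
        f = ThermalFrame(rng.uniform(20, 40, (12, 12)))
        out = smooth(f, 5, 3).temperatures
        assert out.min() >= f.temperatures.min() - 1e-12
        assert out.max() <= f.temperatures.max() + 1e-12

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            smooth(ThermalFrame(np.full((4, 4), 30.0)), 2, 3)


class TestOtsu:
    def test_bimodal_frame_split_exactly(self):
        arr = np.concatenate([np.full(100, 25.0), np.full(100, 35.0)]).reshape(20, 10)
        thr = otsu_threshold(ThermalFrame(arr))
        assert 25.0 < thr < 35.0
        assert ((arr > thr) == (arr == 35.0)).all()

    def test_constant_frame_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(ThermalFrame(np.full((5, 5), 30.0)))

    def test_matches_bruteforce_oracle_on_random_frames(self, rng):
        """The chosen threshold attains the exhaustive-search maximum of the
        between-class-variance objective (ties between equal-variance splits
        may fall anywhere on the flat top of the objective)."""
        for _ in range(60):
            n = int(rng.integers(5, 40))
            vals = rng.normal(30, 4, size=(n, n))
            if rng.random() < 0.5:
                vals[: n // 2] += 8.0
            vals = np.clip(vals, 1, 59)
            thr = otsu_threshold(ThermalFrame(vals))
            thr_bf, var_bf = otsu_bruteforce(vals)
            assert variance_at(vals, thr) == pytest.approx(var_bf, rel=1e-9)
            assert variance_at(vals, thr_bf) == pytest.approx(var_bf, rel=1e-9)


class TestSegment:
    def _ellipse_frame(self, noise_sd=0.0, rng=None):
        rr, cc = np.mgrid[0:80, 0:60]
        mask = ((rr - 40) / 30.0) ** 2 + ((cc - 30) / 20.0) ** 2 <= 1
        arr = np.where(mask, 33.0, 25.0)
        if noise_sd and rng is not None:
            arr = arr + rng.normal(0, noise_sd, arr.shape)
        return ThermalFrame(arr), mask

    def test_recovers_ellipse_exactly_when_noiseless(self):
        frame, truth = self._ellipse_frame()
        got = segment_arm(frame).mask
        np.testing.assert_array_equal(got, truth)

    def test_recovers_ellipse_under_sensor_noise(self, rng):
        frame, truth = self._ellipse_frame(noise_sd=0.05, rng=rng)
        from thermarm.preprocess import smooth as _smooth

        got = segment_arm(_smooth(frame, 3, 3)).mask
        jaccard = (got & truth).sum() / (got | truth).sum()
        assert jaccard >= 0.99

    def test_keeps_largest_of_two_blobs(self):
        arr = np.full((30, 30), 25.0)
        arr[5:20, 5:20] = 33.0   # large blob
        arr[25:28, 25:28] = 33.0  # small blob
        mask = segment_arm(ThermalFrame(arr)).mask
        assert mask[10, 10] and not mask[26, 26]

    def test_fills_holes(self):
        arr = np.full((30, 30), 25.0)
        arr[5:25, 5:25] = 33.0
        arr[14:16, 14:16] = 25.0  # cool hole inside the warm blob
        mask = segment_arm(ThermalFrame(arr)).mask
        assert mask[14, 14]

    def test_mask_override_used_verbatim(self):
        arr = np.full((10, 10), 25.0)
        override = np.zeros((10, 10), bool)
        override[2:5, 2:5] = True
        mask = segment_arm(ThermalFrame(arr), mask_override=override)
        np.testing.assert_array_equal(mask.mask, override)

    def test_constant_frame_fails(self):
        with pytest.raises(DegenerateHistogramError):
            segment_arm(ThermalFrame(np.full((5, 5), 30.0)))


class TestCrop:
    def test_tight_bounding_box(self):
        mask = np.zeros((60, 30), bool)
        mask[10:50, 5:25] = True
        frame = ThermalFrame(np.random.default_rng(0).uniform(25, 35, (60, 30)))
        roi, roi_mask = crop_roi(frame, ArmMask(mask))
        assert roi.shape == (40, 20)
        assert roi_mask.mask.all()

    def test_full_mask_identity(self, rng):
        frame = ThermalFrame(rng.uniform(25, 35, (8, 8)))
        roi, _ = crop_roi(frame, ArmMask(np.ones((8, 8), bool)))
        np.testing.assert_array_equal(roi.temperatures, frame.temperatures)

    def test_single_pixel_mask(self, rng):
        mask = np.zeros((8, 8), bool)
        mask[3, 4] = True
        roi, roi_mask = crop_roi(ThermalFrame(rng.uniform(25, 35, (8, 8))), ArmMask(mask))
        assert roi.shape == (1, 1) and roi_mask.mask.shape == (1, 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(SegmentationError):
            ArmMask(np.zeros((4, 4), bool))
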