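import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.draw import polygon as sk_polygon

from anchorreg import extraction as ex
from anchorreg.errors import DetectionFailureError, InvalidParameterError


def render_wells(positions, shape=(200, 200), depth=0.4, sigma=2.5,
                 background=0.6, bright=None, noise=0.0, seed=0):
    """Minimal local renderer independent of the validation module."""
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for x, y in positions:
        img -= depth * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    for x, y in bright or []:
        img += depth * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, shape)
    return img


@pytest.fixture
def hole_positions():
    rng = np.random.default_rng(4)
    base = np.array([(40 + 55 * i + rng.uniform(-3, 3), 40 + 55 * j + rng.uniform(-3, 3))
                     for i in range(3) for j in range(3)])
    return base[:10] if len(base) > 10 else base


class TestDetectDarkKeypoints:
    def test_flat_image_yields_empty_set(self):
        out = ex.detect_dark_keypoints(np.full((50, 50), 0.3))
        assert out.shape == (0, 2)

    def test_recovers_rendered_holes_within_half_pixel(self, hole_positions):
        img = render_wells(hole_positions)
        cfg = ex.DetectionConfig(blur_sigma=1.0, min_separation=10)
        det = ex.detect_dark_keypoints(img, cfg)
        assert len(det) == len(hole_positions)
        d, _ = cKDTree(det).query(hole_positions)
        assert d.max() < 0.5

    def test_below_mean_filter_excludes_bright_spots(self, hole_positions):
        bright = [(170.0, 30.0), (30.0, 170.0)]
        img = render_wells(hole_positions[:6], bright=bright)
        cfg = ex.DetectionConfig(blur_sigma=1.0, min_separation=8)
        det = ex.detect_dark_keypoints(img, cfg)
        from scipy.ndimage import gaussian_filter

        sm = gaussian_filter(img, 1.0)
        vals = sm[np.round(det[:, 1]).astype(int), np.round(det[:, 0]).astype(int)]
        assert np.all(vals < sm.mean())

    def test_min_separation_keeps_darker_of_conflicting_pair(self):
        # two overlapping wells, one deeper: only the deeper survives
        img = render_wells([(60.0, 60.0)], depth=0.5)
        img -= 0.25 * np.exp(
            -((np.mgrid[0:200, 0:200][1] - 66.0) ** 2
              + (np.mgrid[0:200, 0:200][0] - 60.0) ** 2) / (2 * 2.5**2)
        )
        cfg = ex.DetectionConfig(blur_sigma=1.0, min_separation=10)
        det = ex.detect_dark_keypoints(img, cfg)
        assert len(det) == 1
        assert abs(det[0, 0] - 60.0) < 1.5

    def test_sift_like_multiscale_detector_agrees_on_fixture(self, hole_positions):
        img = render_wells(hole_positions, noise=0.02)
        cfg = ex.DetectionConfig(
            blur_sigma=1.0, min_separation=10, detector="sift_like"
        )
        det = ex.detect_dark_keypoints(img, cfg)
        d, _ = cKDTree(det).query(hole_positions)
        assert d.max() < 0.5

    def test_determinism_identical_inputs_identical_outputs(self, hole_positions):
        img = render_wells(hole_positions, noise=0.03)
        cfg = ex.DetectionConfig(blur_sigma=1.0, min_separation=10)
        a = ex.detect_dark_keypoints(img, cfg)
        b = ex.detect_dark_keypoints(img.copy(), cfg)
        assert np.array_equal(a, b)

    def test_detection_recall_precision_on_snr10_fixture(self, hole_positions):
        img = render_wells(hole_positions, noise=0.04, seed=7)  # SNR 10
        cfg = ex.DetectionConfig(blur_sigma=1.5, min_separation=10)
        det = ex.detect_dark_keypoints(img, cfg)
        d_truth, _ = cKDTree(det).query(hole_positions)
        d_det, _ = cKDTree(hole_positions).query(det)
        assert np.mean(d_truth < 0.5) >= 0.99  # recall
        assert np.mean(d_det < 0.5) >= 0.99  # precision


class TestDetectSquareCorners:
    def test_axis_aligned_square_corners_within_one_pixel(self):
        img = np.zeros((120, 120))
        img[30:70, 40:80] = 1.0  # region outline (39.5..79.5) x (29.5..69.5)
        det = ex.detect_square_corners(img, ex.DetectionConfig(blur_sigma=1.0))
        truth = np.array([[39.5, 29.5], [79.5, 29.5], [79.5, 69.5], [39.5, 69.5]])
        assert np.abs(det.corners - truth).max() < 1.0
        assert np.allclose(det.centroid, [59.5, 49.5], atol=1.0)

    def test_rotated_square_corners_within_one_pixel(self):
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        sq = (np.array([[-20, -20], [20, -20], [20, 20], [-20, 20]])
              @ np.array([[c, -s], [s, c]]).T) + 60
        rr, cc = sk_polygon(sq[:, 1], sq[:, 0], (120, 120))
        img = np.zeros((120, 120))
        img[rr, cc] = 1.0
        det = ex.detect_square_corners(img, ex.DetectionConfig(blur_sigma=1.0))
        d, _ = cKDTree(det.corners).query(sq)
        assert d.max() < 1.0

    def test_corners_counterclockwise_starting_near_origin(self):
        img = np.zeros((100, 100))
        img[20:60, 30:70] = 1.0
        det = ex.detect_square_corners(img, ex.DetectionConfig(blur_sigma=1.0))
        # first corner nearest (0,0); signed area positive (CCW on x,y)
        d0 = np.hypot(det.corners[0, 0], det.corners[0, 1])
        assert d0 == pytest.approx(np.hypot(det.corners[:, 0], det.corners[:, 1]).min())
        x, y = det.corners[:, 0], det.corners[:, 1]
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area2 > 0

    def test_flat_image_raises_detection_failure(self):
        with pytest.raises(DetectionFailureError):
            ex.detect_square_corners(np.full((50, 50), 0.7))

    def test_tiny_component_below_area_fraction_rejected(self):
        img = np.zeros((100, 100))
        img[50, 50] = 1.0
        with pytest.raises(DetectionFailureError):
            ex.detect_square_corners(
                img, ex.DetectionConfig(blur_sigma=0.0, min_area_frac=0.01)
            )


class TestClassifySites:
    def test_bright_spot_present_background_absent(self):
        bright = [(30.0, 30.0), (70.0, 30.0)]
        img = render_wells([], shape=(100, 100), bright=bright, noise=0.01)
        pts = np.array(bright + [(50.0, 70.0), (20.0, 60.0)])
        labels = ex.classify_sites(img, pts, window=2)
        assert [s.label for s in labels] == ["present", "present", "absent", "absent"]

    def test_constant_image_all_labels_identical_present(self):
        labels = ex.classify_sites(np.full((40, 40), 0.5), [(10, 10), (20, 30)])
        assert {s.label for s in labels} == {"present"}

    def test_point_outside_bounds_names_index(self):
        with pytest.raises(InvalidParameterError, match="point 1"):
            ex.classify_sites(np.ones((20, 20)), [(5.0, 5.0), (50.0, 5.0)])

    def test_uniform_background_population_all_absent(self):
        img = render_wells([(30.0, 30.0)], shape=(100, 100), noise=0.01)
        pts = [(70.0, 70.0), (80.0, 20.0), (20.0, 80.0)]
        labels = ex.classify_sites(img, pts, window=2)
        assert {s.label for s in labels} == {"absent"}

    def test_explicit_threshold_overrides_automatic_rule(self):
        img = np.full((30, 30), 0.5)
        labels = ex.classify_sites(img, [(10, 10)], threshold=0.9)
        assert labels[0].label == "absent"
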