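import numpy as np
import pytest
from scipy.spatial import cKDTree

from anchorreg import transforms as tr
from anchorreg import validation as va
from anchorreg.anchor_models import make_lattice_model, si7x7_template
from anchorreg.errors import InvalidParameterError
from anchorreg.estimation import LmedsConfig
from anchorreg.extraction import DetectionConfig, detect_dark_keypoints
from anchorreg.transforms import TransformMatrix
from anchorreg.validation import (
    HomographyMagnitude,
    MetricConfig,
    SweepConfig,
    render_fixture,
)


class TestMetrics:
    def test_mae_identical_sets_is_zero(self):
        p = np.random.default_rng(0).normal(size=(10, 2))
        assert va.mae(p, p) == 0.0

    def test_mae_uniform_three_four_displacement_is_half(self):
        p = np.random.default_rng(1).normal(size=(20, 2))
        assert va.mae(p + [0.3, 0.4], p) == pytest.approx(0.5)

    def test_mae_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(20, 2)), rng.normal(size=(20, 2))
        acc = 0.0
        for i in range(20):
            acc += np.sqrt((a[i, 0] - b[i, 0]) ** 2 + (a[i, 1] - b[i, 1]) ** 2)
        assert va.mae(a, b) == pytest.approx(acc / 20)

    def test_mae_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            va.mae(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_oks_identical_sets_is_one(self):
        p = np.random.default_rng(3).normal(size=(8, 2))
        assert va.oks(p, p) == 1.0

    def test_oks_single_point_at_kernel_scale_is_exp_minus_one(self):
        cfg = MetricConfig(oks_scale=2.0, oks_kappa=0.3)
        d = cfg.oks_scale * cfg.oks_kappa * np.sqrt(2.0)
        assert va.oks([[0.0, 0.0]], [[d, 0.0]], cfg) == pytest.approx(np.exp(-1))

    def test_oks_vanishes_for_large_errors(self):
        assert va.oks([[0.0, 0.0]], [[1e6, 0.0]]) < 1e-12

    @pytest.mark.parametrize(
        "values,expect",
        [([1.0, 1.0, 1.0], 1.0), ([0.5, 0.5], 0.0), ([0.99, 0.5, 0.99, 0.5], 0.5)],
    )
    def test_recall_fraction_above_threshold(self, values, expect):
        assert va.recall_at_oks(values, 0.95) == expect

    def test_recall_empty_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            va.recall_at_oks([], 0.95)


class TestRandomHomography:
    def test_zero_magnitudes_give_identity(self):
        H = va.random_homography(
            np.random.default_rng(0), HomographyMagnitude(0, 0, 0, 0, 0)
        )
        assert np.allclose(H.m, np.eye(3))

    def test_same_seed_same_matrix(self):
        a = va.random_homography(np.random.default_rng(42))
        b = va.random_homography(np.random.default_rng(42))
        assert np.array_equal(a.m, b.m)

    def test_draws_invertible_with_positive_depth_over_extent(self):
        rng = np.random.default_rng(1)
        corners = np.array([[0, 0], [3, 0], [0, 3], [3, 3], [1.5, 1.5]], float)
        for _ in range(2000):
            H = va.random_homography(rng, extent=3.0)
            assert abs(np.linalg.det(H.m)) > 1e-12
            z = np.column_stack([corners, np.ones(5)]) @ H.m[2]
            assert np.all(z[:4] > 0)


class TestNoiseSweep:
    def test_zero_noise_every_sample_exact(self):
        cfg = SweepConfig(noise_stds=(0.0,), point_counts=(4, 9), n_samples=50, seed=1)
        res = va.run_noise_sweep(cfg)
        assert np.all(res.records.oks == 1.0)
        assert res.records.mae.max() < 1e-9

    def test_mean_mae_nondecreasing_in_noise(self):
        cfg = SweepConfig(
            noise_stds=(0.0, 0.05, 0.1), point_counts=(4,), n_samples=1000, seed=2
        )
        s = va.run_noise_sweep(cfg).summary().sort_values("noise_std")
        m = s.mae_mean.to_numpy()
        assert m[0] <= m[1] <= m[2]

    def test_parameter_recovery_at_low_noise_nine_points(self):
        # noise 0.02, 9 points: entrywise |H_est - H_true| < 0.05 in >= 95%
        rng = np.random.default_rng(3)
        model = make_lattice_model(3, 3)
        good = 0
        trials = 200
        from anchorreg.estimation import estimate_homography_lmeds

        for t in range(trials):
            H = va.random_homography(rng, extent=2.0)
            noisy = tr.apply_transform(H, model.points) + rng.normal(
                0, 0.02, (9, 2)
            )
            est = estimate_homography_lmeds(
                model.points, noisy, LmedsConfig(n_samples=200, seed=t)
            )
            if np.abs(est.H.m - H.m).max() < 0.05:
                good += 1
        assert good / trials >= 0.95

    def test_same_seed_bitwise_identical_sweep(self):
        cfg = SweepConfig(
            noise_stds=(0.03,), point_counts=(9,), n_samples=30, seed=7
        )
        a = va.run_noise_sweep(cfg)
        b = va.run_noise_sweep(cfg)
        assert a.records.equals(b.records)

    def test_invalid_point_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            SweepConfig(point_counts=(5,))


class TestRenderFixture:
    def test_zero_noise_extrema_at_model_positions(self):
        model = make_lattice_model(3, 3)
        H = TransformMatrix(np.array([[40.0, 0, 40], [0, 40.0, 40], [0, 0, 1]]))
        img, gt = render_fixture(model, H, shape=(200, 200))
        for x, y in gt.anchor_positions:
            r, c = int(round(y)), int(round(x))
            patch = img[r - 3 : r + 4, c - 3 : c + 4]
            rr, cc = np.unravel_index(np.argmin(patch), patch.shape)
            assert abs(rr - 3) <= 0 and abs(cc - 3) <= 0

    def test_same_seed_identical_images(self):
        model = make_lattice_model(3, 3)
        H = TransformMatrix(np.array([[40.0, 0, 40], [0, 40.0, 40], [0, 0, 1]]))
        a, _ = render_fixture(model, H, shape=(200, 200), snr=10, seed=5)
        b, _ = render_fixture(model, H, shape=(200, 200), snr=10, seed=5)
        assert np.array_equal(a, b)

    def test_points_outside_canvas_listed(self):
        model = make_lattice_model(3, 3)
        H = TransformMatrix(np.array([[100.0, 0, 0], [0, 100.0, 0], [0, 0, 1]]))
        with pytest.raises(InvalidParameterError, match="indices"):
            render_fixture(model, H, shape=(150, 150))

    def test_snr20_fixture_closes_loop_with_detection(self, lattice_scene):
        det = detect_dark_keypoints(
            lattice_scene["img"], DetectionConfig(blur_sigma=1.0, min_separation=10)
        )
        d, _ = cKDTree(det).query(lattice_scene["gt"].anchor_positions)
        assert len(det) == 25
        assert d.max() < 0.5

    def test_defect_list_controls_rendered_subfeatures(self):
        model = make_lattice_model(3, 3)
        tmpl = si7x7_template()
        H = TransformMatrix(np.array([[60.0, 0, 40], [0, 60.0, 40], [0, 0, 1]]))
        img_full, gt = render_fixture(model, H, template=tmpl, shape=(250, 250))
        img_def, _ = render_fixture(
            model, H, template=tmpl, shape=(250, 250), defects=(((0, 0), 2),)
        )
        pos = gt.subfeature_positions[(0, 0)][2]
        r, c = int(round(pos[1])), int(round(pos[0]))
        assert img_full[r, c] > img_def[r, c] + 0.1
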