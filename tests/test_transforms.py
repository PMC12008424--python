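import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anchorreg import transforms as tr
from anchorreg.errors import (
    DegenerateProjectionError,
    InvalidParameterError,
    SingularTransformError,
)
from anchorreg.transforms import AffineParams, TransformMatrix

from conftest import FIG_H


class TestComposeAffine:
    def test_identity_parameters_give_identity_matrix(self):
        A = tr.compose_affine(AffineParams())
        assert np.allclose(A.m, np.eye(3))
        assert A.kind == "affine"

    def test_pure_translation_fills_third_column(self):
        A = tr.compose_affine(AffineParams(x_0=3.0, y_0=-2.0))
        assert np.allclose(A.m[:, 2], [3.0, -2.0, 1.0])

    def test_scale_rotation_maps_unit_y_to_minus_two_x(self):
        # S(2,1) R(pi/2) applied to (0,1): R sends (0,1)->(-1,0), S doubles x
        A = tr.compose_affine(AffineParams(s_x=2, s_y=1, theta=np.pi / 2))
        out = tr.apply_transform(A, (0.0, 1.0))
        assert np.allclose(out, [[-2.0, 0.0]], atol=1e-12)

    def test_factor_order_is_scale_rotate_shear_translate(self):
        # translation happens in pre-rotation coordinates: A p = S R Sh (p+t)
        p = AffineParams(s_x=1.5, s_y=0.5, theta=0.3, a_x=0.1, a_y=-0.2, x_0=2, y_0=1)
        S = np.diag([1.5, 0.5, 1.0])
        c, s = np.cos(0.3), np.sin(0.3)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        Sh = np.array([[1, 0.1, 0], [-0.2, 1, 0], [0, 0, 1]])
        T = np.array([[1, 0, 2], [0, 1, 1], [0, 0, 1]])
        assert np.allclose(tr.compose_affine(p).m, S @ R @ Sh @ T)

    @pytest.mark.parametrize("bad", [dict(s_x=0.0), dict(s_y=-1.0)])
    def test_non_positive_scale_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            AffineParams(**bad)

    def test_affine_closure_projective_row_is_zero(self):
        p = AffineParams(s_x=2.3, s_y=0.7, theta=1.1, a_x=0.4, a_y=0.2, x_0=-5, y_0=9)
        A = tr.compose_affine(p)
        assert A.m[2, 0] == 0 and A.m[2, 1] == 0


class TestApplyTransform:
    def test_identity_leaves_points_unchanged(self):
        pts = np.array([[1.0, 2.0], [-3.0, 0.5]])
        assert np.array_equal(tr.apply_transform(np.eye(3), pts), pts)

    def test_worked_homography_on_100_100(self, worked_homography):
        # z_t = 0.005*100 + 0.001*100 + 1 = 1.6; x_t = 100; y_t = 130
        out = tr.apply_transform(worked_homography, (100.0, 100.0))
        assert np.allclose(out, [[62.5, 81.25]], atol=1e-12)

    def test_affine_subcase_has_unit_homogeneous_coordinate(self):
        A = tr.compose_affine(AffineParams(s_x=3, theta=0.2, x_0=4))
        pts = np.random.default_rng(0).normal(size=(20, 2)) * 100
        homo = np.column_stack([pts, np.ones(20)]) @ A.m.T
        assert np.allclose(homo[:, 2], 1.0)

    def test_point_at_infinity_reports_offending_index(self):
        H = TransformMatrix([[1, 0, 0], [0, 1, 0], [-0.01, 0, 1]])
        with pytest.raises(DegenerateProjectionError) as exc:
            tr.apply_transform(H, [[1.0, 1.0], [100.0, 0.0]])
        assert exc.value.indices == [1]

    def test_projective_scale_invariance(self, worked_homography):
        pts = np.array([[10.0, 20.0], [35.0, 5.0]])
        scaled = TransformMatrix(worked_homography.m * 7.3)
        assert np.allclose(
            tr.apply_transform(worked_homography, pts),
            tr.apply_transform(scaled, pts),
        )


class TestInvertTransform:
    def test_identity_inverts_to_identity(self):
        assert np.allclose(tr.invert_transform(np.eye(3)).m, np.eye(3))

    def test_translation_inverts_to_negated_translation(self):
        A = tr.compose_affine(AffineParams(x_0=3, y_0=-2))
        assert np.allclose(tr.invert_transform(A).m[:, 2], [-3.0, 2.0, 1.0])

    def test_worked_homography_round_trip(self, worked_homography):
        Hinv = tr.invert_transform(worked_homography)
        out = tr.apply_transform(Hinv, (62.5, 81.25))
        assert np.allclose(out, [[100.0, 100.0]], atol=1e-9)
        assert worked_homography.m[2, 2] == 1.0 and Hinv.m[2, 2] == 1.0

    def test_singular_matrix_rejected(self):
        with pytest.raises(SingularTransformError):
            TransformMatrix([[1, 0, 0], [2, 0, 0], [0, 0, 1]])

    def test_double_inversion_restores_entries(self, worked_homography):
        back = tr.invert_transform(tr.invert_transform(worked_homography))
        assert np.allclose(back.m, worked_homography.m, atol=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.tuples(
        st.floats(0.5, 2.0), st.floats(0.5, 2.0), st.floats(-1.0, 1.0),
        st.floats(-0.3, 0.3), st.floats(-0.3, 0.3),
        st.floats(-5.0, 5.0), st.floats(-5.0, 5.0),
    ),
    st.tuples(st.floats(-0.002, 0.002), st.floats(-0.002, 0.002)),
)
def test_composition_consistency_property(affine_vals, gh):
    """apply(A @ B, p) equals apply(A, apply(B, p)) for any pair of maps."""
    A = tr.compose_affine(AffineParams(*affine_vals))
    Bm = np.eye(3)
    Bm[2, 0], Bm[2, 1] = gh
    B = TransformMatrix(Bm)
    pts = np.array([[1.0, 2.0], [-3.0, 4.0], [10.0, -7.0]])
    lhs = tr.apply_transform(tr.chain(A, B), pts)
    rhs = tr.apply_transform(A, tr.apply_transform(B, pts))
    assert np.allclose(lhs, rhs, atol=1e-9)


class TestWarpImage:
    def test_identity_warp_is_bitwise_identical(self):
        img = np.random.default_rng(1).random((30, 40))
        assert np.array_equal(tr.warp_image(img, np.eye(3)), img)

    def test_integer_translation_shifts_columns_and_fills(self):
        img = np.random.default_rng(2).random((20, 25))
        T = tr.compose_affine(AffineParams(x_0=5.0))
        out = tr.warp_image(img, T, fill=-1.0)
        assert np.allclose(out[:, 5:], img[:, :-5])
        assert np.all(out[:, :5] == -1.0)

    def test_warp_and_unwarp_recovers_interior(self, worked_homography):
        rng = np.random.default_rng(3)
        # smooth image so bilinear interpolation error stays small
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random((80, 80)), 3.0)
        img = (img - img.min()) / np.ptp(img)
        Hm = np.array([[1.02, 0.03, 2.0], [-0.02, 0.98, -1.0], [1e-4, -5e-5, 1.0]])
        H = TransformMatrix(Hm)
        warped = tr.warp_image(img, H)
        back = tr.warp_image(warped, tr.invert_transform(H))
        interior = (slice(10, -10), slice(10, -10))
        err = np.abs(back[interior] - img[interior]).mean()
        assert err < 0.02

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            tr.warp_image(np.empty((0, 0)), np.eye(3))

    def test_invalid_output_shape_rejected(self):
        with pytest.raises(InvalidParameterError):
            tr.warp_image(np.ones((5, 5)), np.eye(3), out_shape=(0, 5))


class TestSerialization:
    def test_json_round_trip_preserves_matrix_and_kind(self, worked_homography):
        back = TransformMatrix.from_json(worked_homography.to_json())
        assert back.kind == "homography"
        assert np.allclose(back.m, worked_homography.m)
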