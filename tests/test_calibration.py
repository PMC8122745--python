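"""Checker measurement and thin-plate-spline color-warp behavior."""

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from olivetray.calibration import (
    CheckerLayout,
    ColorWarp,
    ControlPointSet,
    DegenerateControlPointsError,
    RoiBoundsError,
    WarpFitError,
    apply_warp,
    fit_warp,
    load_reference_table,
    measure_checker,
)
from olivetray.synthetic import ColorCast, SceneConfig, apply_cast, generate_scene

REFERENCE = load_reference_table()


def flat_checker(colors: np.ndarray, patch: int = 12) -> tuple[np.ndarray, CheckerLayout]:
    """Render a gap-free 4x6 grid of the given 24 colors."""
    img = np.zeros((4 * patch, 6 * patch, 3))
    rois = []
    for i in range(4):
        for j in range(6):
            img[i * patch : (i + 1) * patch, j * patch : (j + 1) * patch] = colors[
                i * 6 + j
            ]
            rois.append((i * patch, j * patch, patch, patch))
    return img, CheckerLayout(patch_rois=rois, sampling_fraction=0.5)


class TestMeasureChecker:
    def test_uniform_rois_measure_exactly(self):
        img, layout = flat_checker(REFERENCE)
        points = measure_checker(img, layout, REFERENCE)
        np.testing.assert_allclose(points.measured, REFERENCE, atol=1e-12)

    def test_rendered_scene_checker_matches_reference_within_quantization(self):
        cfg = SceneConfig(
            height=200, width=260, olive_count=0, leaf_count=0, noise_sigma=0.0,
            checker=True, seed=1,
        )
        img, truth = generate_scene(cfg)
        points = measure_checker(img, truth.checker_layout, REFERENCE)
        assert np.abs(points.measured - points.reference).max() <= 1 / 255

    def test_affine_cast_shifts_measured_colors_predictably(self):
        cast = ColorCast(matrix=0.8 * np.eye(3), offset=[0.1, 0.1, 0.1])
        img, layout = flat_checker(REFERENCE)
        points = measure_checker(apply_cast(img, cast), layout, REFERENCE)
        np.testing.assert_allclose(
            points.measured, 0.8 * REFERENCE + 0.1, atol=1 / 255
        )

    def test_roi_out_of_bounds_raises(self):
        img, layout = flat_checker(REFERENCE)
        bad = list(layout.patch_rois)
        bad[7] = (1000, 0, 12, 12)
        with pytest.raises(RoiBoundsError, match="7"):
            measure_checker(img, CheckerLayout(patch_rois=bad), REFERENCE)

    def test_duplicate_measured_colors_raise_and_name_patches(self):
        measured = REFERENCE.copy()
        measured[5] = measured[2]
        with pytest.raises(DegenerateControlPointsError, match="2"):
            ControlPointSet(measured=measured, reference=REFERENCE)

    def test_layout_from_corners_recovers_gapless_grid(self):
        patch = 12
        img, _ = flat_checker(REFERENCE, patch=patch)
        corners = [(0, 0), (0, 6 * patch), (4 * patch, 6 * patch), (4 * patch, 0)]
        layout = CheckerLayout.from_corners(corners, roi_fraction=0.5)
        points = measure_checker(img, layout, REFERENCE)
        np.testing.assert_allclose(points.measured, REFERENCE, atol=1e-12)


class TestFitWarp:
    def test_identity_control_pairs_give_identity_warp(self):
        points = ControlPointSet(measured=REFERENCE, reference=REFERENCE)
        warp = fit_warp(points)
        assert np.abs(warp(REFERENCE) - REFERENCE).max() <= 1e-9
        rng = np.random.default_rng(0)
        colors = rng.uniform(0, 1, (50, 3))
        assert np.abs(warp(colors) - colors).max() <= 1e-9

    @pytest.mark.parametrize("kernel", ["linear", "thin_plate"])
    def test_affine_cast_recovered_by_affine_part_alone(self, kernel):
        rng = np.random.default_rng(42)
        A = 0.8 * np.eye(3) + rng.uniform(-0.05, 0.05, (3, 3))
        b = rng.uniform(0.02, 0.08, 3)
        measured = REFERENCE @ A.T + b
        warp = fit_warp(
            ControlPointSet(measured=measured, reference=REFERENCE), kernel_name=kernel
        )
        assert np.linalg.norm(warp.radial_weights) <= 1e-6

    @pytest.mark.parametrize("kernel", ["linear", "thin_plate"])
    def test_exact_interpolation_of_nonlinear_cast(self, kernel):
        cast = ColorCast(matrix=0.85 * np.eye(3), offset=[0.05, 0.1, 0.02],
                         gamma=[1.2, 0.9, 1.05])
        measured = apply_cast(REFERENCE.reshape(1, 24, 3), cast).reshape(24, 3)
        points = ControlPointSet(measured=measured, reference=REFERENCE)
        warp = fit_warp(points, kernel_name=kernel)
        assert np.abs(warp(measured) - REFERENCE).max() <= 1e-6

    def test_side_conditions_hold(self):
        cast = ColorCast(matrix=0.8 * np.eye(3), offset=[0.1, 0.05, 0.0], gamma=1.3)
        measured = apply_cast(REFERENCE.reshape(1, 24, 3), cast).reshape(24, 3)
        warp = fit_warp(ControlPointSet(measured=measured, reference=REFERENCE))
        assert np.abs(warp.radial_weights.sum(axis=0)).max() <= 1e-8
        assert np.abs(warp.centers.T @ warp.radial_weights).max() <= 1e-8

    def test_matches_scipy_rbf_interpolator(self):
        """Independent cross-check: same interpolant as scipy's RBF solver."""
        cast = ColorCast(matrix=0.9 * np.eye(3), offset=[0.02, 0.05, 0.01], gamma=1.4)
        measured = apply_cast(REFERENCE.reshape(1, 24, 3), cast).reshape(24, 3)
        points = ControlPointSet(measured=measured, reference=REFERENCE)
        rng = np.random.default_rng(7)
        queries = rng.uniform(0, 1, (100, 3))
        for mine, scipy_kernel in [("linear", "linear"),
                                   ("thin_plate", "thin_plate_spline")]:
            warp = fit_warp(points, kernel_name=mine)
            oracle = RBFInterpolator(measured, REFERENCE, kernel=scipy_kernel, degree=1)
            np.testing.assert_allclose(warp(queries), oracle(queries), atol=1e-8)

    def test_residual_monotone_in_regularization(self):
        cast = ColorCast(matrix=0.8 * np.eye(3), offset=[0.1, 0.0, 0.05], gamma=1.5)
        measured = apply_cast(REFERENCE.reshape(1, 24, 3), cast).reshape(24, 3)
        points = ControlPointSet(measured=measured, reference=REFERENCE)
        residuals = []
        for lam in [0.0, 1e-4, 1e-2, 1.0]:
            warp = fit_warp(points, regularization=lam)
            residuals.append(np.abs(warp(measured) - REFERENCE).max())
        assert all(a <= b + 1e-12 for a, b in zip(residuals, residuals[1:]))

    def test_negative_regularization_rejected(self):
        points = ControlPointSet(measured=REFERENCE, reference=REFERENCE)
        with pytest.raises(ValueError):
            fit_warp(points, regularization=-1.0)

    def test_near_duplicate_centers_raise_fit_error(self):
        # the smooth thin-plate kernel is singular for coincident centers;
        # a separation just past the degeneracy gate must still be rejected
        measured = REFERENCE.copy()
        measured[1] = measured[0] + 2e-9
        with pytest.raises(WarpFitError, match="regularization"):
            fit_warp(ControlPointSet(measured=measured, reference=REFERENCE),
                     kernel_name="thin_plate")


class TestApplyWarp:
    def test_identity_warp_preserves_any_image(self):
        warp = fit_warp(ControlPointSet(measured=REFERENCE, reference=REFERENCE))
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (20, 30, 3))
        assert np.abs(warp(img) - img).max() <= 1e-9

    def test_calibration_restores_cast_checker(self):
        cast = ColorCast(matrix=0.8 * np.eye(3), offset=[0.1, 0.1, 0.1])
        img, layout = flat_checker(REFERENCE)
        cast_img = apply_cast(img, cast)
        points = measure_checker(cast_img, layout, REFERENCE)
        warp = fit_warp(points)
        calibrated = apply_warp(warp, cast_img)
        re_measured = measure_checker(calibrated, layout, REFERENCE)
        assert np.abs(re_measured.measured - REFERENCE).max() <= 2 / 255

    def test_control_points_map_exactly(self):
        cast = ColorCast(matrix=np.eye(3) * 0.9, offset=[0.05, 0.0, 0.02], gamma=1.1)
        measured = apply_cast(REFERENCE.reshape(1, 24, 3), cast).reshape(24, 3)
        warp = fit_warp(ControlPointSet(measured=measured, reference=REFERENCE))
        pixel = np.broadcast_to(measured[10], (1, 1, 3))
        assert np.abs(apply_warp(warp, pixel) - REFERENCE[10]).max() <= 1e-6

    def test_refit_on_calibrated_checker_is_near_identity(self):
        cast = ColorCast(matrix=0.82 * np.eye(3), offset=[0.08, 0.04, 0.1], gamma=1.2)
        img, layout = flat_checker(REFERENCE)
        calibrated = apply_warp(fit_warp(measure_checker(apply_cast(img, cast),
                                                         layout, REFERENCE)), apply_cast(img, cast))
        second = fit_warp(measure_checker(calibrated, layout, REFERENCE))
        assert np.abs(second(REFERENCE) - REFERENCE).max() <= 2 / 255

    def test_unfitted_warp_rejected(self):
        with pytest.raises(TypeError):
            apply_warp("not a warp", np.zeros((4, 4, 3)))


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        cast = ColorCast(matrix=0.85 * np.eye(3), offset=[0.03, 0.06, 0.01], gamma=1.3)
        measured = apply_cast(REFERENCE.reshape(1, 24, 3), cast).reshape(24, 3)
        warp = fit_warp(ControlPointSet(measured=measured, reference=REFERENCE))
        path = tmp_path / "warp.json"
        warp.to_json(path)
        loaded = ColorWarp.from_json(path)
        rng = np.random.default_rng(9)
        colors = rng.uniform(0, 1, (64, 3))
        np.testing.assert_array_equal(warp(colors), loaded(colors))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            fit_warp(ControlPointSet(measured=REFERENCE, reference=REFERENCE),
                     kernel_name="gaussian")
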