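"""Signal prediction, ROI/exposure solvers, binning oracles and ranking."""

import numpy as np
import pytest

from bruisebands import (
    BruiseEffect,
    CameraModel,
    HyperCube,
    SpectralAxis,
    make_apple_scene,
)
from bruisebands.calibration import ReflectanceCube
from bruisebands.resolution_optimizer import (
    BandROI,
    BinningCombination,
    acquire_combination,
    bin_cube,
    bin_spectra,
    enumerate_combinations,
    evaluate_combination,
    predict_signal,
    solve_exposure,
    solve_roi_width,
)

FLAT_RATE = 50_000.0  # DN/s/row


@pytest.fixture()
def flat_camera():
    """Camera with (numerically) flat spectral throughput."""
    return CameraModel(peak_rate_dn_per_s=FLAT_RATE, sigma_blue_nm=1e9,
                       sigma_red_nm=1e9)


@pytest.fixture()
def wide_axis():
    return SpectralAxis.default()


class TestPredictSignal:
    def test_linear_in_exposure_below_saturation(self, flat_camera, wide_axis):
        dn1, sat1 = predict_signal(flat_camera, wide_axis, 553.9, 1, 0.05)
        dn2, sat2 = predict_signal(flat_camera, wide_axis, 553.9, 1, 0.10)
        assert not sat1 and not sat2
        assert dn2 == pytest.approx(2 * dn1)

    @pytest.mark.parametrize("rows", [1, 3, 7])
    def test_flat_throughput_closed_form_matches_row_sum(self, flat_camera,
                                                         wide_axis, rows):
        exposure = 1e-3
        dn, _ = predict_signal(flat_camera, wide_axis, 700.0, rows, exposure)
        assert dn == pytest.approx(FLAT_RATE * rows * exposure)

    def test_beyond_full_scale_capped_and_flagged(self, flat_camera, wide_axis):
        dn, sat = predict_signal(flat_camera, wide_axis, 700.0, 9, 10.0)
        assert sat and dn == flat_camera.full_scale_dn

    def test_roi_leaving_axis_rejected(self, flat_camera, wide_axis):
        with pytest.raises(ValueError, match="axis"):
            predict_signal(flat_camera, wide_axis, 400.0, 99, 0.01)


class TestSolvers:
    def test_roi_width_matches_brute_force_sweep(self, flat_camera, wide_axis):
        exposure, target = 0.004, 0.6
        roi = solve_roi_width(flat_camera, wide_axis, 700.0, exposure, target)
        # oracle: sweep odd widths and keep the first that reaches the target
        rows = 1
        while True:
            dn, _ = predict_signal(flat_camera, wide_axis, 700.0, rows, exposure,
                                   0.99)
            if dn / flat_camera.full_scale_dn >= target:
                break
            rows += 2
        assert roi.rows == rows
        assert roi.achieved_fraction >= target
        assert roi.roi_width_nm == rows * wide_axis.sampling_interval_nm

    def test_solved_width_non_increasing_in_exposure(self, wide_axis):
        cam = CameraModel()
        widths = [
            solve_roi_width(cam, wide_axis, 774.2, e, 0.5).rows
            for e in (0.005, 0.01, 0.02, 0.04)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_unreachable_target_reports_max_achievable(self, wide_axis):
        cam = CameraModel()
        with pytest.raises(ValueError, match="max achievable"):
            solve_roi_width(cam, wide_axis, 424.5, 1e-4, 0.9)

    def test_exposure_closed_form_single_flat_row(self, flat_camera, wide_axis):
        e = solve_exposure(flat_camera, wide_axis, 700.0, rows=1,
                           target_fraction=0.9)
        assert e == pytest.approx(
            0.9 * flat_camera.full_scale_dn / (FLAT_RATE * 0.99)
        )

    def test_exposure_halves_when_rows_double(self, flat_camera, wide_axis):
        e1 = solve_exposure(flat_camera, wide_axis, 700.0, rows=3)
        e2 = solve_exposure(flat_camera, wide_axis, 700.0, rows=6)
        assert e2 == pytest.approx(e1 / 2)

    def test_inverse_law_exposure_times_throughput_constant(self, wide_axis):
        cam = CameraModel()
        products = []
        for rows in (1, 3, 5, 9):
            e = solve_exposure(cam, wide_axis, 553.9, rows)
            idx = wide_axis.index_of(553.9)
            half = rows // 2
            rate = cam.throughput(
                wide_axis.wavelengths_nm[idx - half: idx + half + 1]
            ).sum()
            products.append(e * rate)
        assert np.allclose(products, products[0])


class TestEnumerate:
    def test_single_level_single_fraction(self, wide_axis):
        cam = CameraModel()
        combos, _ = enumerate_combinations(
            cam, wide_axis, (553.9, 774.2, 424.5),
            reference_rows_levels=(3,), fraction_grid=(0.5,),
        )
        assert len(combos) <= 1
        if combos:
            c = combos[0]
            assert c.rois[0].center_nm == 553.9
            assert c.rois[0].target_fraction == 0.9
            assert {r.center_nm for r in c.rois[1:]} == {774.2, 424.5}

    def test_default_grid_yields_several_feasible_combinations(self, wide_axis):
        cam = CameraModel()
        combos, skipped = enumerate_combinations(cam, wide_axis,
                                                 (553.9, 774.2, 424.5))
        assert 2 <= len(combos) <= 12
        assert skipped  # some (exposure, fraction) cells are infeasible
        exposures = sorted({c.exposure_s for c in combos}, reverse=True)
        assert len(exposures) >= 2  # several exposure levels survive

    def test_achieved_fraction_monotone_in_rows(self, wide_axis):
        cam = CameraModel()
        fracs = [
            predict_signal(cam, wide_axis, 774.2, rows, 0.01, 0.99)[0]
            / cam.full_scale_dn
            for rows in (1, 3, 5, 7, 9)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_reference_band_must_be_a_key_wavelength(self, wide_axis):
        cam = CameraModel()
        with pytest.raises(ValueError, match="reference"):
            enumerate_combinations(cam, wide_axis, (774.2, 424.5),
                                   reference_center_nm=553.9)


def _combo(axis, rois, exposure=0.01):
    return BinningCombination(1, exposure, tuple(rois))


class TestBinCube:
    def test_raw_binning_equals_brute_force_row_sums(self, rng):
        axis = SpectralAxis(np.linspace(400, 1000, 32))
        cam = CameraModel()
        data = rng.integers(0, 500, (8, 8, 32)).astype(float)
        cube = HyperCube(data, axis, "raw")
        rois = [BandROI(axis.wavelengths_nm[c], rows, rows * 19.35, 0.5, 0.5)
                for c, rows in ((5, 3), (16, 5), (28, 1))]
        out, centers = bin_cube(cube, _combo(axis, rois), cam)
        for j, (c, rows) in enumerate(((5, 3), (16, 5), (28, 1))):
            half = rows // 2
            manual = data[:, :, c - half: c + half + 1].sum(axis=2)
            assert np.array_equal(out[:, :, j], manual)

    def test_raw_binning_clips_at_full_scale(self, rng):
        axis = SpectralAxis(np.linspace(400, 1000, 16))
        cam = CameraModel()
        cube = HyperCube(np.full((2, 2, 16), 9000.0), axis, "raw")
        roi = BandROI(axis.wavelengths_nm[8], 5, 5.0, 0.9, 1.0, True)
        out, _ = bin_cube(cube, _combo(axis, [roi]), cam)
        assert np.all(out == cam.full_scale_dn)

    def test_single_row_roi_reproduces_original_band(self, rng):
        axis = SpectralAxis(np.linspace(400, 1000, 16))
        data = rng.uniform(0, 1, (4, 4, 16))
        cube = ReflectanceCube(data, axis, np.ones_like(data, bool))
        roi = BandROI(axis.wavelengths_nm[7], 1, 1.0, 0.9, 0.9)
        out, _ = bin_cube(cube, _combo(axis, [roi]))
        assert np.allclose(out[:, :, 0], data[:, :, 7])

    def test_constant_reflectance_mean_preserves_value(self):
        axis = SpectralAxis(np.linspace(400, 1000, 16))
        data = np.full((3, 3, 16), 0.37)
        cube = ReflectanceCube(data, axis, np.ones_like(data, bool))
        roi = BandROI(axis.wavelengths_nm[8], 7, 7.0, 0.9, 0.9)
        out, _ = bin_cube(cube, _combo(axis, [roi]))
        assert np.allclose(out, 0.37)

    def test_binning_reduces_noise_variance_as_one_over_rows(self, rng):
        axis = SpectralAxis(np.linspace(400, 1000, 32))
        rows = 9
        sigma = 0.02
        data = 0.5 + rng.normal(0, sigma, (60, 60, 32))
        cube = ReflectanceCube(data, axis, np.ones_like(data, bool))
        flat_cam = CameraModel(sigma_blue_nm=1e9, sigma_red_nm=1e9)
        roi = BandROI(axis.wavelengths_nm[16], rows, float(rows), 0.9, 0.9)
        out, _ = bin_cube(cube, _combo(axis, [roi]), flat_cam)
        assert out[:, :, 0].var() == pytest.approx(sigma**2 / rows, rel=0.2)

    def test_bin_spectra_matches_cube_binning(self, rng):
        axis = SpectralAxis(np.linspace(400, 1000, 32))
        cam = CameraModel()
        data = rng.uniform(0.1, 0.9, (4, 5, 32))
        cube = ReflectanceCube(data, axis, np.ones_like(data, bool))
        roi = BandROI(axis.wavelengths_nm[10], 5, 5.0, 0.9, 0.9)
        combo = _combo(axis, [roi])
        from_cube, _ = bin_cube(cube, combo, cam)
        from_spectra = bin_spectra(data.reshape(-1, 32), axis, combo, cam,
                                   white_reflectance=1.0)
        assert np.allclose(from_cube.reshape(-1, 1), from_spectra)


class TestAcquireAndScore:
    def test_acquisition_reflectance_close_to_truth(self, model):
        scene = make_apple_scene(model, BruiseEffect.from_severity("high"),
                                 seed=13)
        cam = CameraModel()
        axis = model.axis
        combos, _ = enumerate_combinations(cam, axis, (553.9, 774.2, 424.5),
                                           reference_rows_levels=(3,),
                                           fraction_grid=(0.9,))
        ms, centers = acquire_combination(scene, combos[0], cam,
                                          np.random.default_rng(1))
        truth = scene.reflectance_truth.data
        apple = scene.truth.apple_mask
        for j, c in enumerate(centers):
            ref_band = truth[:, :, axis.index_of(c, tol_nm=np.inf)]
            err = np.abs(ms[:, :, j][apple] - ref_band[apple]).mean()
            assert err < 0.05, (c, err)

    def test_sound_only_cohort_accuracy_counts_clean_apples(self, model, study):
        from bruisebands import generate_cohort

        scenes = generate_cohort(2, groups=("sound",), seed=31, model=model)
        cam = CameraModel()
        combos, _ = enumerate_combinations(
            cam, model.axis, (553.9, 774.2, 424.5),
            reference_rows_levels=(3,), fraction_grid=(0.9,),
        )
        report = evaluate_combination(combos[0], scenes, "LDA", study.dataset,
                                      cam, seed=0)
        clean = np.mean([not d for d in report.decisions])
        assert report.apple_accuracy == pytest.approx(clean)

    def test_saturated_combination_scores_worse(self, model, study):
        from bruisebands import generate_cohort

        scenes = generate_cohort(1, groups=("high", "sound"), seed=17,
                                 model=model)
        cam = CameraModel()
        combos, _ = enumerate_combinations(
            cam, model.axis, (553.9, 774.2, 424.5),
            reference_rows_levels=(3,), fraction_grid=(0.9,),
        )
        good = combos[0]
        # same ROIs at 30x the exposure: the apple signal clips hard
        bad = BinningCombination(99, good.exposure_s * 30.0, good.rois)
        r_good = evaluate_combination(good, scenes, "QDA", study.dataset, cam, 0)
        r_bad = evaluate_combination(bad, scenes, "QDA", study.dataset, cam, 0)
        assert r_bad.pixel_accuracy < r_good.pixel_accuracy


class TestBandROIValidation:
    def test_even_row_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            BandROI(553.9, 2, 10.0, 0.5, 0.5)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="achieved_fraction"):
            BandROI(553.9, 1, 5.0, 0.5, 1.5)
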