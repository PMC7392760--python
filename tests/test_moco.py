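import numpy as np
import pytest
from scipy.fft import dctn

from dixonperf.dixon import separate_water_fat
from dixonperf.metrics import temporal_smoothness, trajectory_error
from dixonperf.moco import (NoDynamicContentError, RigidTransformSeries,
                            RoiBox, apply_transforms, auto_roi, nonrigid_correct,
                            pca_reference, register_rigid_pair, residual_complexity,
                            rigid_correct_series, run_moco)
from dixonperf.transforms import (compose_rigid, invert_rigid, rigid_matrix,
                                  warp_rigid)


@pytest.fixture(scope="module")
def fat_and_roi(moving_phantom):
    spec, series, truth = moving_phantom
    pair = separate_water_fat(series)
    roi = auto_roi(pair.water)
    return spec, pair, roi, truth


@pytest.fixture(scope="module")
def static_pair_128(moving_phantom):
    """Motion-free render of the 128x128 phantom (pristine frames for
    single-pair registration oracles)."""
    import dataclasses
    from dixonperf.phantom import make_phantom
    spec, _, _ = moving_phantom
    s_series, s_truth = make_phantom(dataclasses.replace(spec, motion=None))
    return separate_water_fat(s_series), s_truth


class TestAutoRoi:
    def test_box_covers_heart(self, fat_and_roi):
        _, _, roi, truth = fat_and_roi
        assert roi.contains_fraction(truth.heart_mask) >= 0.95

    def test_constant_series_raises(self):
        with pytest.raises(NoDynamicContentError):
            auto_roi(np.ones((12, 32, 32)))

    def test_margin_monotonic(self, fat_and_roi):
        _, pair, _, _ = fat_and_roi
        small = auto_roi(pair.water, margin=2)
        big = auto_roi(pair.water, margin=6)
        assert big.width >= small.width and big.height >= small.height
        assert big.x0 <= small.x0 and big.y0 <= small.y0


class TestRigidTransforms:
    def test_compose_invert_roundtrip(self):
        c = (31.5, 31.5)
        p = (2.0, -3.0, 0.1)
        pid = compose_rigid(p, invert_rigid(p, c), c)
        assert np.allclose(pid, (0, 0, 0), atol=1e-12)

    def test_composition_matches_sequential_warps(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(rng.random((64, 64)), 2)
        p, q = (1.5, -2.0, 0.05), (-0.5, 1.0, -0.03)
        c = (31.5, 31.5)
        double = warp_rigid(warp_rigid(img, p, center=c), q, center=c)
        single = warp_rigid(img, compose_rigid(p, q, c), center=c)
        inner = (slice(8, -8),) * 2
        assert np.linalg.norm((double - single)[inner]) / \
            np.linalg.norm(single[inner]) < 0.02

    def test_identity_series_and_composition_invariant(self):
        s = RigidTransformSeries.identity(5, center=(10, 10))
        s.iterations = [np.zeros((5, 3)), np.zeros((5, 3))]
        assert np.allclose(s.composed_from_iterations(), 0)


class TestRegisterRigidPair:
    def test_identity(self, fat_and_roi):
        _, pair, roi, _ = fat_and_roi
        p, diag = register_rigid_pair(pair.fat[5], pair.fat[5], roi)
        assert abs(p[0]) < 0.05 and abs(p[1]) < 0.05
        assert abs(np.rad2deg(p[2])) < 0.05

    def test_known_translation_recovered(self, fat_and_roi):
        _, pair, roi, _ = fat_and_roi
        c = ((pair.fat.shape[1] - 1) / 2.0,) * 2
        moved = warp_rigid(pair.fat[5], invert_rigid((4.0, -2.0, 0.0), c))
        p, _ = register_rigid_pair(moved, pair.fat[5], roi)
        assert abs(p[0] - 4.0) < 0.25 and abs(p[1] + 2.0) < 0.25

    def test_known_rotation_recovered(self, fat_and_roi, static_pair_128):
        _, _, roi, _ = fat_and_roi
        pair, _ = static_pair_128
        c = ((pair.fat.shape[1] - 1) / 2.0,) * 2
        moved = warp_rigid(pair.fat[5], invert_rigid((0.0, 0.0, np.deg2rad(3.0)), c))
        p, _ = register_rigid_pair(moved, pair.fat[5], roi)
        assert abs(np.rad2deg(p[2]) - 3.0) < 0.3


class TestRigidCorrectSeries:
    def test_motionless_series_near_identity(self, static_phantom):
        _, series, _ = static_phantom
        pair = separate_water_fat(series)
        roi = auto_roi(pair.water)
        transforms, _, _ = rigid_correct_series(pair.fat[:12], roi, n_iterations=2)
        assert np.abs(transforms.tx).max() < 0.1
        assert np.abs(transforms.ty).max() < 0.1
        assert np.rad2deg(np.abs(transforms.theta)).max() < 0.1

    def test_trajectory_recovery_on_moving_phantom(self, fat_and_roi):
        spec, pair, roi, truth = fat_and_roi
        transforms, _, report = rigid_correct_series(pair.fat, roi, n_iterations=3)
        traj = truth.trajectory
        rms_t, rms_r = trajectory_error(transforms.tx, transforms.ty,
                                        transforms.theta, traj.tx, traj.ty,
                                        traj.theta)
        assert rms_t < 0.5
        assert rms_r < 0.5
        # MSE of the corrected stack to the evolving mean is non-increasing
        trace = report["mse_trace"]
        assert all(b <= a * (1 + 1e-6) for a, b in zip(trace, trace[1:]))

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            rigid_correct_series(np.zeros((4, 8, 8)), RoiBox(0, 0, 8, 8),
                                 n_iterations=0)


class TestApplyTransforms:
    def test_identity(self):
        rng = np.random.default_rng(0)
        stack = rng.random((3, 16, 16))
        out = apply_transforms(stack, RigidTransformSeries.identity(3, (7.5, 7.5)))
        assert np.max(np.abs(out - stack)) < 1e-12

    def test_integer_shift_nearest(self):
        rng = np.random.default_rng(1)
        stack = rng.random((2, 16, 16))
        t = RigidTransformSeries(np.full(2, 2.0), np.zeros(2), np.zeros(2), (7.5, 7.5))
        out = apply_transforms(stack, t, interpolation="nearest")
        assert np.array_equal(out[0, :, :-2], stack[0, :, 2:])

    def test_truth_inverse_restores_myocardium(self, fat_and_roi):
        spec, pair, roi, truth = fat_and_roi
        traj = truth.trajectory
        t = RigidTransformSeries(traj.tx, traj.ty, traj.theta,
                                 ((spec.grid_size - 1) / 2.0,) * 2)
        # warp the moved myocardial mask back with the true parameters
        myo = truth.myo_mask.astype(float)
        n = len(traj)
        dices = []
        c = t.center
        for k in range(n):
            moved = warp_rigid(myo, invert_rigid((traj.tx[k], traj.ty[k],
                                                  traj.theta[k]), c), order=0)
            restored = warp_rigid(moved, (traj.tx[k], traj.ty[k], traj.theta[k]),
                                  center=c, order=0) > 0.5
            inter = (restored & truth.myo_mask).sum()
            dices.append(2 * inter / (restored.sum() + truth.myo_mask.sum()))
        assert min(dices) > 0.95

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            apply_transforms(np.zeros((3, 8, 8)),
                             RigidTransformSeries.identity(4, (3.5, 3.5)))


class TestPcaReference:
    def test_rank3_series_reconstructed_exactly(self):
        rng = np.random.default_rng(1)
        modes = rng.normal(size=(3, 100))
        weights = rng.normal(size=(20, 3))
        stack = (weights @ modes).reshape(20, 10, 10)
        rec = pca_reference(stack, 3)
        assert np.linalg.norm(rec - stack) / np.linalg.norm(stack) < 1e-10

    def test_energy_capture_monotone_in_components(self):
        rng = np.random.default_rng(2)
        stack = rng.normal(size=(12, 8, 8))
        errs = [np.linalg.norm(pca_reference(stack, k) - stack)
                for k in range(1, 12)]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_matches_independent_sklearn_pca(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(3)
        stack = rng.normal(size=(15, 6, 6))
        rec = pca_reference(stack, 4)
        x = stack.reshape(15, -1)
        p = PCA(n_components=4)
        rec2 = p.inverse_transform(p.fit_transform(x)).reshape(stack.shape)
        assert np.linalg.norm(rec - rec2) / np.linalg.norm(rec2) < 1e-10

    def test_too_many_components_raise(self):
        with pytest.raises(ValueError):
            pca_reference(np.zeros((5, 4, 4)), 5)

    def test_synthetic_reference_tracks_motion_free_enhancement(
            self, fat_and_roi, static_pair_128):
        spec, pair, roi, truth = fat_and_roi
        transforms, _, _ = rigid_correct_series(pair.fat, roi, n_iterations=2)
        corrected = apply_transforms(pair.water, transforms)
        ys, xs = roi.slices
        ref = pca_reference(corrected[:, ys, xs], 3)
        s_pair, s_truth = static_pair_128
        s_water = s_pair.water[:, ys, xs]
        # erode the mask: partial-volume pixels at the blood border mix in
        # the much brighter LV signal under any sub-pixel misalignment
        from scipy.ndimage import binary_erosion
        myo = binary_erosion(s_truth.myo_mask)[ys, xs]
        r = np.corrcoef(ref[:, myo].ravel(), s_water[:, myo].ravel())[0, 1]
        assert r > 0.99


class TestResidualComplexity:
    def test_zero_residual_costs_zero(self):
        assert residual_complexity(np.zeros((8, 8))) == 0.0

    def test_sign_symmetry(self):
        rng = np.random.default_rng(4)
        r = rng.normal(size=(12, 12))
        assert residual_complexity(r, 0.1) == pytest.approx(
            residual_complexity(-r, 0.1), rel=1e-12)

    def test_matches_bruteforce_dct_formula_on_8x8(self):
        rng = np.random.default_rng(5)
        for alpha in (0.01, 0.05, 1.0):
            for _ in range(5):
                r = rng.normal(size=(8, 8))
                q = dctn(r, norm="ortho")
                brute = float(np.sum(np.log(q ** 2 / alpha + 1.0)))
                assert residual_complexity(r, alpha) == pytest.approx(brute, rel=1e-12)

    def test_smooth_ramp_cheaper_than_white_noise(self):
        ramp = np.outer(np.linspace(-1, 1, 16), np.ones(16))
        rng = np.random.default_rng(6)
        noise = rng.normal(size=(16, 16))
        noise *= np.linalg.norm(ramp) / np.linalg.norm(noise)
        assert residual_complexity(ramp, 0.05) < residual_complexity(noise, 0.05)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            residual_complexity(np.ones((4, 4)), alpha=0.0)


class TestNonrigidCorrect:
    def test_aligned_input_stays_put(self, fat_and_roi):
        _, pair, roi, _ = fat_and_roi
        ys, xs = roi.slices
        crop = pair.water[10:14, ys, xs]
        deform, corrected = nonrigid_correct(crop, crop)
        assert deform.mean_displacement() < 0.2

    def test_known_smooth_warp_recovered(self, fat_and_roi):
        _, pair, roi, _ = fat_and_roi
        ys, xs = roi.slices
        frames = pair.water[18:22, ys, xs]
        ny, nx = frames.shape[1:]
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        dy = 2.0 * np.sin(np.pi * yy / ny) * np.sin(np.pi * xx / nx)
        dx = -1.5 * np.sin(np.pi * xx / nx) * np.sin(np.pi * yy / ny)
        from scipy.ndimage import map_coordinates
        warped = np.stack([map_coordinates(f, [yy + dy, xx + dx], order=1,
                                           mode="nearest") for f in frames])
        deform, corrected = nonrigid_correct(warped, frames)
        # warped(x) = frames(x + d); the corrective field must approach -d
        inner = (slice(8, -8), slice(8, -8))
        errs = []
        for t in range(len(deform)):
            ey, ex = deform.dense_field(t)
            errs.append(np.mean(np.hypot((ey + dy)[inner], (ex + dx)[inner])))
        assert np.mean(errs) < 0.5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            nonrigid_correct(np.zeros((2, 8, 8)), np.zeros((2, 8, 9)))


class TestRunMoco:
    def test_motionless_phantom_is_noop(self, static_phantom):
        _, series, truth = static_phantom
        pair = separate_water_fat(series)
        corrected, transforms, deform, report = run_moco(pair)
        nrmse = np.linalg.norm(corrected - pair.water) / np.linalg.norm(pair.water)
        assert nrmse < 0.01

    def test_full_pipeline_improves_alignment_and_smoothness(self, noisy_moving_phantom):
        spec, series, truth = noisy_moving_phantom
        pair = separate_water_fat(series)
        corrected, transforms, deform, report = run_moco(pair)
        myo = truth.myo_mask
        sm_none = temporal_smoothness(pair.water, myo).mean
        water_rigid = apply_transforms(pair.water, transforms)
        sm_rigid = temporal_smoothness(water_rigid, myo).mean
        sm_full = temporal_smoothness(corrected, myo).mean
        assert sm_full < sm_none
        assert sm_full <= sm_rigid

        # myocardial alignment against the static truth: move the mask with
        # the true motion (rigid + dense), then restore it with the full
        # estimated correction (rigid transforms + FFD on the ROI crop)
        from scipy.ndimage import map_coordinates
        c = transforms.center
        roi = report["roi"]
        ys, xs = roi.slices
        ny, nx = corrected.shape[1:]
        yyf, xxf = np.meshgrid(np.arange(ny, dtype=float),
                               np.arange(nx, dtype=float), indexing="ij")
        traj = truth.trajectory
        dices = []
        for k in range(len(transforms)):
            p_true = (traj.tx[k], traj.ty[k], traj.theta[k])
            tdy, tdx = traj.dense_field(k, (ny, nx))
            m = np.linalg.inv(rigid_matrix(p_true, c))
            cy = m[0, 0] * (yyf - tdy) + m[0, 1] * (xxf - tdx) + m[0, 2]
            cx = m[1, 0] * (yyf - tdy) + m[1, 1] * (xxf - tdx) + m[1, 2]
            moved = map_coordinates(truth.myo_mask.astype(float), [cy, cx], order=0)
            restored = warp_rigid(moved, transforms.params(k), center=c, order=0)
            if deform is not None:
                dy, dx = deform.dense_field(k)
                crop = restored[ys, xs]
                yy, xx = np.meshgrid(np.arange(crop.shape[0], dtype=float),
                                     np.arange(crop.shape[1], dtype=float),
                                     indexing="ij")
                restored[ys, xs] = map_coordinates(crop, [yy + dy, xx + dx], order=0)
            rb = restored > 0.5
            inter = (rb & truth.myo_mask).sum()
            dices.append(2 * inter / (rb.sum() + truth.myo_mask.sum()))
        assert np.mean(dices) > 0.9
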