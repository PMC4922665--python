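import numpy as np
import pytest
from scipy import ndimage
from sklearn.base import clone

from leafsen.degrade import ChannelKernelSet, identity_kernels, simulate_degradation
from leafsen.restore import (
    ChartLayout,
    ColorDistortionCorrector,
    CorrectionMatrix,
    apply_correction,
    build_design_matrix,
    calibrate_from_chart,
    estimate_correction,
    estimate_ground_truth,
    render_chart,
)
from leafsen.synthetic import DEFAULT_PALETTE, SyntheticSceneSpec, generate_scene


def brute_force_design_row(img, r, c, L):
    """Enumerate one neighborhood row: channel-major, then row, then col."""
    H, W, C = img.shape
    h = L // 2
    row = []
    for ch in range(C):
        for dr in range(-h, h + 1):
            for dc in range(-h, h + 1):
                rr = min(max(r + dr, 0), H - 1)
                cc = min(max(c + dc, 0), W - 1)
                row.append(img[rr, cc, ch])
    return np.array(row)


class TestDesignMatrix:
    def test_kernel_one_is_pixel_matrix(self, rng):
        img = rng.random((5, 4, 3))
        d = build_design_matrix(img, 1)
        np.testing.assert_array_equal(d.entries, img.reshape(-1, 3))

    def test_column_count_is_l_squared_times_channels(self, rng):
        d = build_design_matrix(rng.random((10, 10, 3)), 5)
        assert d.entries.shape == (100, 75)

    def test_replicate_padded_corner_row(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None] / 4.0
        d = build_design_matrix(img, 3)
        np.testing.assert_allclose(
            d.entries[0] * 4.0, [1, 1, 2, 1, 1, 2, 3, 3, 4]
        )

    def test_every_row_matches_enumeration_oracle(self, rng):
        img = rng.random((4, 5, 2))
        d = build_design_matrix(img, 3)
        for r in range(4):
            for c in range(5):
                np.testing.assert_allclose(
                    d.entries[r * 5 + c], brute_force_design_row(img, r, c, 3)
                )

    def test_design_matrix_product_equals_correlation(self, rng):
        """The patch arrangement and the forward degradation agree: X @ w
        reproduces the cross-channel correlation for any kernel set."""
        img = rng.random((7, 6, 3))
        w = rng.random((3, 3, 3, 3)) * 0.03  # outputs stay below the clip
        d = build_design_matrix(img, 3)
        out = simulate_degradation(img, ChannelKernelSet(w, 0.0), seed=0)
        for co in range(3):
            vec = w[co].reshape(-1)  # channel-major, row, col — same order
            np.testing.assert_allclose(
                (d.entries @ vec).reshape(7, 6), out[:, :, co], atol=1e-12
            )

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            build_design_matrix(rng.random((4, 4, 3)), 2)


class TestEstimateCorrection:
    def test_undistorted_pair_yields_identity(self, rng):
        img = rng.random((20, 20, 3))
        X = build_design_matrix(img, 1)
        C = estimate_correction(X, img.reshape(-1, 3), ridge=0.0)
        np.testing.assert_allclose(C.entries, np.eye(3), atol=1e-10)
        assert C.fit_residual < 1e-8

    def test_scalar_closed_form(self, rng):
        # single channel, X = 2 G: least squares a = sum(xg)/sum(x^2) = 0.5
        g = rng.random((6, 6, 1)) * 0.5
        x = np.clip(2 * g, 0, 1)
        X = build_design_matrix(x, 1)
        C = estimate_correction(X, g.reshape(-1, 1), ridge=0.0)
        assert C.entries[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_svd_pseudoinverse_oracle(self, rng):
        for _ in range(10):
            S = int(rng.integers(40, 200))
            M = int(rng.integers(4, 30))
            X = rng.random((S, M))
            G = rng.random((S, 3))
            C = estimate_correction(X, G, ridge=0.0)
            C_svd = np.linalg.pinv(X) @ G
            rel = np.abs(C.entries - C_svd).max() / np.abs(C_svd).max()
            assert rel < 1e-6

    def test_perturbing_solution_never_improves_objective(self, rng):
        X = rng.random((80, 12))
        G = rng.random((80, 3))
        ridge = 0.01
        C = estimate_correction(X, G, ridge=ridge).entries

        def objective(c):
            return np.sum((G - X @ c) ** 2) + ridge * np.sum(c**2)

        base = objective(C)
        for idx in [(0, 0), (5, 1), (11, 2)]:
            for eps in (1e-3, -1e-3):
                C2 = C.copy()
                C2[idx] += eps
                assert objective(C2) >= base

    def test_rank_deficient_advises_ridge(self):
        X = np.ones((30, 4))  # flat image: rank 1
        G = np.ones((30, 3)) * 0.5
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            estimate_correction(X, G, ridge=0.0)
        # a positive ridge resolves it
        C = estimate_correction(X, G, ridge=1e-6)
        assert np.isfinite(C.entries).all()

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="rows"):
            estimate_correction(rng.random((10, 4)), rng.random((9, 3)))


class TestApplyCorrection:
    def test_identity_matrix_is_identity_operator(self, rng):
        img = rng.random((6, 6, 3))
        C = CorrectionMatrix(entries=np.eye(3), kernel_size=1, channels=3)
        np.testing.assert_allclose(apply_correction(img, C), img, atol=1e-12)

    def test_matches_per_pixel_dot_product_oracle(self, rng):
        img = rng.random((3, 3, 3))
        entries = rng.standard_normal((27, 3)) * 0.1
        C = CorrectionMatrix(entries=entries, kernel_size=3, channels=3)
        out = apply_correction(img, C, clip=False)
        for r in range(3):
            for c in range(3):
                row = brute_force_design_row(img, r, c, 3)
                np.testing.assert_allclose(out[r, c], row @ entries, atol=1e-12)

    def test_training_residual_is_consistent(self, green_scene, distortion_kernels):
        clean = green_scene.clean_image
        deg = simulate_degradation(clean, distortion_kernels, seed=0)
        X = build_design_matrix(deg, 3)
        C = estimate_correction(X, clean.reshape(-1, 3), ridge=1e-8)
        R = apply_correction(deg, C, clip=False)
        resid = np.sqrt(np.mean((R - clean) ** 2))
        assert resid == pytest.approx(C.fit_residual, abs=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        C = CorrectionMatrix(entries=np.eye(3), kernel_size=1, channels=3)
        with pytest.raises(ValueError, match="channel"):
            apply_correction(rng.random((4, 4, 1)), C)


class TestRecovery:
    def test_shift_degradation_inverted_to_machine_precision(self, rng):
        """A pure one-pixel shift has an exact FIR inverse, so fitting at
        capacity recovers the clean image almost exactly away from borders."""
        img = rng.random((32, 32, 3))
        w = np.zeros((3, 3, 3, 3))
        for ch in range(3):
            w[ch, ch, 1, 2] = 1.0  # shift left by one column
        deg = simulate_degradation(img, ChannelKernelSet(w, 0.0), seed=0)
        X = build_design_matrix(deg, 3)
        # fit on interior pixels only: border rows see the padding clamp,
        # where the shift has no exact inverse
        interior = np.zeros((32, 32), bool)
        interior[2:-2, 2:-2] = True
        sel = interior.ravel()
        C = estimate_correction(X.entries[sel], img.reshape(-1, 3)[sel], ridge=0.0)
        rec = apply_correction(deg, C, clip=False)
        assert np.abs(rec - img)[4:-4, 4:-4].max() < 1e-8

    def test_blur_recovered_below_percent_rmse(self, senescent_scene, distortion_kernels):
        clean = senescent_scene.clean_image
        deg = simulate_degradation(clean, distortion_kernels, seed=0)
        X = build_design_matrix(deg, 5)
        C = estimate_correction(X, clean.reshape(-1, 3), ridge=1e-8)
        rec = apply_correction(deg, C)
        interior = np.zeros(clean.shape[:2], bool)
        interior[4:-4, 4:-4] = True
        rmse = np.sqrt(np.mean((rec[interior] - clean[interior]) ** 2))
        assert rmse < 0.01


class TestCorrectorEstimator:
    def test_sklearn_param_interface(self):
        est = ColorDistortionCorrector(kernel_size=7, ridge=0.1)
        assert est.get_params()["kernel_size"] == 7
        est2 = clone(est).set_params(ridge="auto")
        assert est2.get_params()["ridge"] == "auto"

    def test_fit_transform_restores(self, green_scene, distortion_kernels):
        clean = green_scene.clean_image
        deg = simulate_degradation(clean, distortion_kernels, seed=1)
        est = ColorDistortionCorrector(kernel_size=5).fit(deg, clean)
        rest = est.transform(deg)
        assert np.sqrt(np.mean((rest - clean) ** 2)) < np.sqrt(
            np.mean((deg - clean) ** 2)
        )
        assert est.fit_residual_ == est.correction_.fit_residual

    def test_fits_on_multiple_pairs(self, rng):
        imgs = [rng.random((10, 10, 3)) for _ in range(2)]
        est = ColorDistortionCorrector(kernel_size=1, ridge=0.0).fit(imgs, imgs)
        np.testing.assert_allclose(est.correction_.entries, np.eye(3), atol=1e-8)

    def test_subsample_is_seeded(self, green_scene, distortion_kernels):
        clean = green_scene.clean_image
        deg = simulate_degradation(clean, distortion_kernels, seed=1)
        fits = [
            ColorDistortionCorrector(kernel_size=3, subsample=0.3, random_state=5)
            .fit(deg, clean)
            .correction_.entries
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0], fits[1])

    def test_transform_before_fit_raises(self, rng):
        with pytest.raises(AttributeError, match="fit"):
            ColorDistortionCorrector().transform(rng.random((4, 4, 3)))


class TestGroundTruthEstimation:
    @staticmethod
    def uniform_green_scene(seed=21):
        pal = dict(DEFAULT_PALETTE)
        pal["light_green"] = (0.11, 0.36, 0.09)  # young plant: near-uniform color
        return generate_scene(
            SyntheticSceneSpec(image_size=(160, 160), leaf_count=5,
                               leaf_length=(45.0, 75.0), palette=pal, seed=seed)
        )

    def test_sharp_scene_interior_preserved(self):
        truth = self.uniform_green_scene()
        target, mask = estimate_ground_truth(
            truth.clean_image, background_samples=[(0, 16, 0, 160)],
            override_mask=truth.plant_mask,
        )
        img = target.entries.reshape(truth.clean_image.shape)
        interior = ndimage.binary_erosion(truth.plant_mask, iterations=3)
        if interior.any():
            err = np.abs(img[interior] - truth.clean_image[interior]).mean()
            assert err < 0.05  # within the generator's color jitter

    def test_border_colors_improve_on_degraded_scene(self, distortion_kernels):
        truth = self.uniform_green_scene()
        deg = simulate_degradation(truth.clean_image, distortion_kernels, seed=4)
        target, _ = estimate_ground_truth(
            deg, background_samples=[(0, 16, 0, 160)],
            override_mask=truth.plant_mask,
        )
        img = target.entries.reshape(deg.shape)
        border = truth.plant_mask & ~ndimage.binary_erosion(
            truth.plant_mask, iterations=2
        )
        err_deg = np.abs(deg[border] - truth.clean_image[border]).mean()
        err_est = np.abs(img[border] - truth.clean_image[border]).mean()
        assert err_est < err_deg

    def test_override_mask_contract(self):
        truth = self.uniform_green_scene()
        _, mask = estimate_ground_truth(
            truth.clean_image, background_samples=[(0, 16, 0, 160)],
            override_mask=truth.plant_mask,
        )
        assert np.array_equal(mask, truth.plant_mask)

    def test_requires_background_or_override(self):
        truth = self.uniform_green_scene()
        with pytest.raises(ValueError, match="background"):
            estimate_ground_truth(truth.clean_image)

    def test_empty_segmentation_rejected(self):
        flat = np.full((32, 32, 3), 0.1)
        with pytest.raises(RuntimeError, match="empty"):
            estimate_ground_truth(
                flat, background_samples=[(0, 8, 0, 32)],
                override_mask=np.zeros((32, 32), bool),
            )


class TestChartCalibration:
    @staticmethod
    def layout(margin=0.05, rng=None):
        rng = rng or np.random.default_rng(0)
        colors = rng.uniform(0.05, 0.95, size=(4, 6, 3))
        return ChartLayout(origin=(20, 20), cell_size=(28, 28),
                           colors=colors, margin=margin)

    def test_clean_chart_gives_identity(self):
        layout = self.layout()
        chart = render_chart(layout, (256, 256))
        X, G = calibrate_from_chart(chart, layout, kernel_size=1)
        C = estimate_correction(X, G, ridge=0.0)
        np.testing.assert_allclose(C.entries, np.eye(3), atol=1e-8)

    def test_degraded_chart_restores_held_out_scene(self, distortion_kernels):
        layout = self.layout()
        chart = render_chart(layout, (256, 256))
        chart_deg = simulate_degradation(chart, distortion_kernels, seed=5)
        X, G = calibrate_from_chart(chart_deg, layout, kernel_size=5)
        C = estimate_correction(X, G, ridge="auto")
        held = generate_scene(
            SyntheticSceneSpec(image_size=(160, 160), leaf_count=5,
                               leaf_length=(45.0, 75.0),
                               senescent_fraction=0.2, seed=23)
        )
        hdeg = simulate_degradation(held.clean_image, distortion_kernels, seed=6)
        hrest = apply_correction(hdeg, C)
        rmse = lambda a: np.sqrt(np.mean((a - held.clean_image) ** 2))
        assert rmse(hrest) < rmse(hdeg)

    def test_half_cell_margin_rejected(self):
        layout = self.layout(margin=0.5)
        chart = render_chart(layout, (256, 256))
        with pytest.raises(ValueError, match="interior"):
            calibrate_from_chart(chart, layout, kernel_size=3)

    def test_out_of_bounds_layout_rejected(self):
        layout = self.layout()
        with pytest.raises(ValueError, match="bounds"):
            render_chart(layout, (100, 100))


def test_matrix_file_round_trip(tmp_path, rng):
    entries = rng.standard_normal((27, 3))
    C = CorrectionMatrix(entries=entries, kernel_size=3, channels=3, ridge=1.5e-7)
    path = tmp_path / "c.txt"
    C.save(path)
    back = CorrectionMatrix.load(path)
    assert back.kernel_size == 3 and back.channels == 3
    assert back.ridge == pytest.approx(1.5e-7, rel=1e-12)
    np.testing.assert_allclose(back.entries, entries, rtol=1e-12)
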