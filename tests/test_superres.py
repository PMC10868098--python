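"""Localization microscopy: detection, Gaussian fitting, rendering."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.special import ndtr

import fishquant as fq
from fishquant.errors import DimensionError, InvalidParameterError
from fishquant.simulate import emitter_image
from fishquant.stackio import empty_localizations


class TestProjection:
    def test_identical_frames_project_to_themselves(self, rng):
        frame = rng.uniform(0, 10, (16, 16))
        stack = fq.FrameStack(np.stack([frame] * 4))
        assert np.allclose(fq.widefield_projection(stack, "mean"), frame)

    def test_mean_of_two_frames(self):
        f1, f2 = np.zeros((4, 4)), np.full((4, 4), 2.0)
        stack = fq.FrameStack(np.stack([f1, f2]))
        assert np.allclose(fq.widefield_projection(stack), 1.0)

    def test_sub_diffraction_doublet_projects_to_one_peak(self):
        # two loci 150 nm apart: the diffraction-limited projection has one maximum
        img = emitter_image((32, 32), [[1525, 1610, 1e5], [1675, 1610, 1e5]], 130, 100)
        peaks = (img == ndimage.maximum_filter(img, 3)) & (img > 0.1 * img.max())
        _, n_regions = ndimage.label(peaks, structure=np.ones((3, 3), dtype=int))
        assert n_regions == 1


class TestDetection:
    def test_zero_frame_yields_no_candidates(self):
        assert fq.detect_candidates(np.zeros((16, 16)), tau=0.0) == []

    def test_single_psf_detected_at_peak(self):
        img = emitter_image((24, 24), [[1250, 1050, 10000]], 130, 100)
        assert fq.detect_candidates(img, tau=1.0) == [(10, 12)]

    def test_grid_of_nine_spots_all_detected(self):
        emitters = [[x * 100.0, y * 100.0, 10000.0] for x in (6.5, 16.5, 26.5) for y in (6.5, 16.5, 26.5)]
        img = emitter_image((33, 33), emitters, 130, 100)
        assert len(fq.detect_candidates(img, tau=1.0)) == 9

    def test_close_maxima_merged_to_brighter(self):
        img = np.zeros((16, 16))
        img[8, 8] = 10.0
        img[8, 9] = 8.0
        assert fq.detect_candidates(img, tau=1.0, min_separation_px=2) == [(8, 8)]


def _scipy_gaussian_fit(window, sigma0):
    """Independent single-spot fit via scipy.curve_fit on the same model."""
    w = window.shape[0]
    edges = np.arange(w + 1, dtype=float)

    def model(_, flux, x, y, s, b):
        ex = np.diff(ndtr((edges - x) / s))
        ey = np.diff(ndtr((edges - y) / s))
        return (flux * np.outer(ey, ex) + b).ravel()

    p0 = [window.sum() - w * w * window.min(), w / 2, w / 2, sigma0, window.min()]
    popt, _ = curve_fit(model, None, window.ravel(), p0=p0, maxfev=5000)
    return popt


class TestGaussianFit:
    def test_noiseless_spot_recovered_exactly(self):
        x, y = 1037.0, 1281.0
        frame = emitter_image((21, 21), [[x, y, 5000]], 130, 100) + 10.0
        rec = fq.fit_gaussian_spot(frame, (12, 10), window_px=9)
        assert rec["x_nm"] == pytest.approx(x, abs=1e-4)
        assert rec["y_nm"] == pytest.approx(y, abs=1e-4)
        assert rec["sigma_nm"] == pytest.approx(130.0, abs=1e-4)
        assert rec["photons"] == pytest.approx(5000.0, rel=1e-6)

    def test_agrees_with_scipy_curve_fit(self, rng):
        frame = emitter_image((15, 15), [[730, 770, 5000]], 130, 100) + 10.0
        noisy = rng.poisson(frame).astype(float)
        rec = fq.fit_gaussian_spot(noisy, (7, 7), window_px=9)
        popt = _scipy_gaussian_fit(noisy[3:12, 3:12], 1.3)
        assert rec["x_nm"] == pytest.approx((3 + popt[1]) * 100, abs=0.5)
        assert rec["y_nm"] == pytest.approx((3 + popt[2]) * 100, abs=0.5)
        assert rec["photons"] == pytest.approx(popt[0], rel=5e-3)

    def test_flat_window_rejected(self):
        assert fq.fit_gaussian_spot(np.full((15, 15), 5.0), (7, 7)) is None

    def test_localization_rmse_and_sqrt_n_scaling(self, rng):
        def rmse(photons, n=60):
            errs = []
            for _ in range(n):
                clean = emitter_image((15, 15), [[730, 770, photons]], 130, 100) + 10.0
                rec = fq.fit_gaussian_spot(rng.poisson(clean).astype(float), (7, 7), window_px=9)
                if rec:
                    errs.append((rec["x_nm"] - 730) ** 2 + (rec["y_nm"] - 770) ** 2)
            return np.sqrt(np.mean(errs))

        r5k = rmse(5000)
        assert r5k < 20.0
        assert rmse(80000) < r5k  # precision improves with photon count


class TestLocalizeStack:
    def test_zero_stack_yields_empty_table(self):
        stack = fq.FrameStack(np.zeros((5, 32, 32), dtype=np.uint16))
        table = fq.localize_stack(stack, threshold=10.0, subtract_static_background=False)
        assert len(table) == 0

    def test_blinking_locus_recovered_on_most_on_frames(self):
        rng = np.random.default_rng(3)
        n_frames, p_on = 300, 0.2
        x, y = 1615.0, 1423.0
        frames = np.empty((n_frames, 32, 32), dtype=np.uint16)
        on = rng.random(n_frames) < p_on
        for t in range(n_frames):
            em = np.array([[x, y, 1500.0]]) if on[t] else np.zeros((0, 3))
            frames[t] = fq.synthesize_frame(em, 130, 100, np.full((32, 32), 20.0), 2.0, seed=rng)
        stack = fq.FrameStack(frames)
        table = fq.localize_stack(stack, threshold=10.0, subtract_static_background=True)
        hits = 0
        for t in np.nonzero(on)[0]:
            rows = table[table["frame"] == t]
            if len(rows) and np.hypot(rows["x_nm"] - x, rows["y_nm"] - y).min() < 50:
                hits += 1
        assert hits >= 0.9 * on.sum()
        assert len(table) == len(table.drop_duplicates())


class TestRendering:
    def test_single_localization_single_pixel(self):
        table = empty_localizations()
        table.loc[0] = [0, 1000.0, 1000.0, 130.0, 1000.0, 0.0, 5.0]
        img = fq.render_superres(table, 20.0, "histogram", extent_nm=(2000, 2000))
        assert img.shape == (100, 100)
        assert img[50, 50] == 1 and img.sum() == 1

    def test_histogram_conserves_counts(self, rng):
        n = 500
        table = empty_localizations()
        for k in range(n):
            table.loc[k] = [0, rng.uniform(0, 3000), rng.uniform(0, 3000), 130, 1000, 0, 5]
        img = fq.render_superres(table, 20.0, "histogram", extent_nm=(3000, 3000))
        assert img.sum() == n

    def test_gaussian_mode_conserves_counts_within_one_percent(self, rng):
        table = empty_localizations()
        for k in range(100):
            table.loc[k] = [0, rng.uniform(500, 2500), rng.uniform(500, 2500), 130, 1000, 0, 15]
        img = fq.render_superres(table, 20.0, "gaussian", extent_nm=(3000, 3000))
        assert img.sum() == pytest.approx(100, rel=0.01)

    def test_resolvability_contrast_between_renders(self, rng):
        # two loci 150 nm apart: distinct at 20 nm rendering, merged at 200 nm
        table = empty_localizations()
        for k in range(200):
            locus = k % 2
            table.loc[k] = [
                k,
                1010.0 + 150.0 * locus + rng.normal(0, 3),
                1010.0 + rng.normal(0, 3),
                130.0,
                1500.0,
                0.0,
                5.0,
            ]

        def n_components(img):
            _, n = ndimage.label(img >= img.max() / 2.0, structure=np.ones((3, 3), dtype=int))
            return n

        fine = fq.render_superres(table, 20.0, "histogram", extent_nm=(2000, 2000))
        coarse = fq.render_superres(table, 200.0, "histogram", extent_nm=(2000, 2000))
        assert n_components(fine) == 2
        assert n_components(coarse) == 1

    def test_empty_table_renders_zero_image(self):
        img = fq.render_superres(empty_localizations(), 20.0, extent_nm=(1000, 1000))
        assert img.shape == (50, 50) and img.sum() == 0

    def test_invalid_render_pixel_rejected(self):
        with pytest.raises(InvalidParameterError):
            fq.render_superres(empty_localizations(), 0.0)
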