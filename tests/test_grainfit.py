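import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from sai import (FitConfig, GrainSet, cost, fit_frame, fit_stack,
                 render_grainset, render_guess)
from sai.grainfit import grain_sigma_px
from sai.optics import FWHM_PER_SIGMA
from sai.reconstruct import _fwhm_of_profile


def gs(amps, rows, cols, sigma, frame=0):
    return GrainSet(amplitudes=amps, rows=rows, cols=cols,
                    grain_sigma_px=sigma, frame_index=frame)


def analytic_guess(grains: GrainSet, sigma_h: float, shape) -> np.ndarray:
    """Closed form: Gaussian grain conv Gaussian PSF = wider Gaussian.

    Variances add; the unit-sum PSF rescales the peak by
    sigma_S^2 / (sigma_S^2 + sigma_h^2).  Independent oracle for the
    rendering path (which uses an explicit FFT convolution).
    """
    s2 = grains.grain_sigma_px ** 2 + sigma_h ** 2
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    out = np.zeros(shape)
    for a, r, c in zip(grains.amplitudes, grains.rows, grains.cols):
        out += (a * grains.grain_sigma_px ** 2 / s2 *
                np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * s2)))
    return out


class TestRendering:
    def test_empty_set_renders_zero(self):
        img = render_grainset(gs([], [], [], 2.0), (16, 16))
        assert not np.any(img)

    def test_single_grain_peak_amplitude(self):
        img = render_grainset(gs([3.0], [8.0], [9.0], 2.0), (17, 18))
        assert img[8, 9] == pytest.approx(3.0)
        assert img.max() == pytest.approx(3.0)

    def test_integral_additivity_against_analytic_gaussian(self):
        # two distant grains: the image integral equals sum of 2 pi sigma^2 A
        sigma = 2.0
        img = render_grainset(gs([2.0, 5.0], [20.3, 60.1], [25.7, 58.9],
                                 sigma), (90, 90))
        expect = 2 * np.pi * sigma ** 2 * (2.0 + 5.0)
        assert img.sum() == pytest.approx(expect, rel=1e-6)

    def test_guess_matches_analytic_convolution(self, small_cfg, small_psf):
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        grains = gs([4.0, 1.5], [30.2, 41.8], [33.9, 28.4], sigma_s)
        rendered = render_guess(grains, small_psf, (72, 72))
        oracle = analytic_guess(grains, small_psf.sigma_px, (72, 72))
        assert np.allclose(rendered, oracle, atol=5e-4 * oracle.max())

    def test_guess_width_is_quadrature_sum(self, small_cfg, small_psf):
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        grains = gs([1.0], [36.0], [36.0], sigma_s)
        img = render_guess(grains, small_psf, (73, 73))
        measured = _fwhm_of_profile(img[36], 1.0)
        fwhm_s = sigma_s * FWHM_PER_SIGMA
        expect = np.hypot(fwhm_s, small_psf.fwhm_px)
        assert measured == pytest.approx(expect, rel=0.02)

    def test_guess_linear_in_amplitude(self, small_cfg, small_psf):
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        g1 = render_guess(gs([1.0], [20.0], [20.0], sigma_s), small_psf,
                          (41, 41))
        g2 = render_guess(gs([2.0], [20.0], [20.0], sigma_s), small_psf,
                          (41, 41))
        assert np.allclose(g2, 2.0 * g1)


class TestCost:
    def test_identity_gives_zero(self, rng):
        img = rng.random((9, 9))
        assert cost(img, img) == 0.0

    def test_hand_case(self):
        assert cost(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])) == 2.0

    def test_permutation_invariance(self, rng):
        a, b = rng.random((6, 6)), rng.random((6, 6))
        perm = rng.permutation(36)
        assert cost(a, b) == pytest.approx(
            cost(a.ravel()[perm].reshape(6, 6),
                 b.ravel()[perm].reshape(6, 6)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cost(np.zeros((2, 2)), np.zeros((3, 3)))


class TestFitFrame:
    def test_null_frame_gives_empty_fit(self, small_cfg, small_psf):
        res = fit_frame(np.zeros((48, 48)), small_psf, small_cfg,
                        FitConfig(seed=0), k_start=10)
        assert res.grain_set.k == 0
        assert res.cost_trace[-1] == 0.0

    def test_single_grain_localization(self, small_cfg, small_psf):
        # noise-free single high-intensity grain: centre within 0.2 S,
        # dominant amplitude within 10%, on a clear majority of seeds
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        truth = gs([5.0], [31.4], [29.8], sigma_s)
        hm = render_guess(truth, small_psf, (64, 64))
        s_px = small_cfg.speckle_size_px
        hits = 0
        for seed in range(20):
            res = fit_frame(hm, small_psf, small_cfg, FitConfig(seed=seed),
                            k_start=1)
            dom = int(np.argmax(res.grain_set.amplitudes))
            err = np.hypot(res.grain_set.rows[dom] - 31.4,
                           res.grain_set.cols[dom] - 29.8)
            amp_ok = abs(res.grain_set.amplitudes[dom] - 5.0) < 0.5
            hits += (err < 0.2 * s_px) and amp_ok
        assert hits > 10

    def test_two_grain_localization(self, small_cfg, small_psf):
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        s_px = small_cfg.speckle_size_px
        truth_pos = [(24.0, 26.0), (24.0 + 3 * s_px, 26.0 + 1.0)]
        truth = gs([4.0, 6.0], [p[0] for p in truth_pos],
                   [p[1] for p in truth_pos], sigma_s)
        hm = render_guess(truth, small_psf, (64, 64))
        hits = 0
        for seed in range(7):
            res = fit_frame(hm, small_psf, small_cfg, FitConfig(seed=seed),
                            k_start=2)
            ok = True
            for r0, c0 in truth_pos:
                d = np.hypot(res.grain_set.rows - r0, res.grain_set.cols - c0)
                w = res.grain_set.amplitudes > 0.2 * res.grain_set.amplitudes.max()
                ok &= np.any(d[w] < 0.3 * s_px)
            hits += ok
        assert hits >= 4

    def test_overspecified_start_still_localizes_centroid(self, small_cfg,
                                                          small_psf):
        # K_start from the area formula over-counts; the amplitude-weighted
        # centroid of the surviving grains is what the average image uses
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        truth = gs([5.0], [30.0], [33.0], sigma_s)
        hm = render_guess(truth, small_psf, (64, 64))
        res = fit_frame(hm, small_psf, small_cfg, FitConfig(seed=1), k_start=8)
        a = res.grain_set.amplitudes
        r = np.sum(a * res.grain_set.rows) / a.sum()
        c = np.sum(a * res.grain_set.cols) / a.sum()
        assert np.hypot(r - 30.0, c - 33.0) < 0.2 * small_cfg.speckle_size_px

    def test_matches_exhaustive_grid_search(self, small_cfg, small_psf):
        # independent oracle: exhaustive 0.25 px centre grid with per-centre
        # least-squares amplitude, on a noise-free single-grain frame
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        truth = gs([3.0], [20.6], [19.2], sigma_s)
        hm = render_guess(truth, small_psf, (40, 40))
        s2 = sigma_s ** 2 + small_psf.sigma_px ** 2
        famp = sigma_s ** 2 / s2
        rr, cc = np.mgrid[0:40, 0:40].astype(float)
        best = (np.inf, None, None, None)
        for r0 in np.arange(18.0, 23.25, 0.25):
            for c0 in np.arange(17.0, 22.25, 0.25):
                unit = famp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                     / (2 * s2))
                a = float(np.sum(hm * unit) / np.sum(unit * unit))
                f = float(np.sum((hm - a * unit) ** 2))
                if f < best[0]:
                    best = (f, r0, c0, a)
        _, r_star, c_star, a_star = best
        hits = 0
        for seed in range(10):
            # fixed model order (no birth/death), initial grain confined to
            # the blob core: pure descent vs the exhaustive grid oracle
            res = fit_frame(hm, small_psf, small_cfg,
                            FitConfig(seed=seed, birth_death_rate=0),
                            k_start=1, support_threshold=0.3 * hm.max())
            dom = int(np.argmax(res.grain_set.amplitudes))
            hits += (abs(res.grain_set.rows[dom] - r_star) <= 0.25 and
                     abs(res.grain_set.cols[dom] - c_star) <= 0.25 and
                     abs(res.grain_set.amplitudes[dom] - a_star)
                     <= 0.05 * a_star)
        assert hits >= 9

    def test_birth_recovers_grain_from_empty_start(self, small_cfg, small_psf):
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        truth = gs([5.0], [30.0], [30.0], sigma_s)
        hm = render_guess(truth, small_psf, (64, 64))
        res = fit_frame(hm, small_psf, small_cfg, FitConfig(seed=0), k_start=0)
        assert res.grain_set.k >= 1
        assert res.n_births >= 1
        dom = int(np.argmax(res.grain_set.amplitudes))
        assert np.hypot(res.grain_set.rows[dom] - 30.0,
                        res.grain_set.cols[dom] - 30.0) < 1.0

    def test_non_finite_input_rejected(self, small_cfg, small_psf):
        bad = np.zeros((16, 16))
        bad[3, 3] = np.nan
        with pytest.raises(ValueError):
            fit_frame(bad, small_psf, small_cfg, FitConfig(), k_start=1)

    def test_cost_trace_monotone_non_increasing(self, small_cfg, small_psf,
                                                rng):
        hm = np.clip(rng.normal(0.0, 1.0, (48, 48)), 0, None)
        res = fit_frame(hm, small_psf, small_cfg, FitConfig(seed=2), k_start=20)
        assert np.all(np.diff(res.cost_trace) <= 1e-9 * res.cost_trace[0])
        assert res.cost_trace[-1] <= res.cost_trace[0]


class TestFitStack:
    def test_determinism_and_per_frame_independence(self, small_cfg,
                                                    small_psf):
        rng = np.random.default_rng(4)
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        frames = np.stack([
            render_guess(gs([3.0], [float(r)], [float(c)], sigma_s),
                         small_psf, (48, 48))
            for r, c in rng.uniform(15, 33, (3, 2))])
        a = fit_stack(frames, small_psf, small_cfg, FitConfig(seed=11), 1)
        b = fit_stack(frames, small_psf, small_cfg, FitConfig(seed=11), 1)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.grain_set.amplitudes,
                                  fb.grain_set.amplitudes)
            assert np.array_equal(fa.grain_set.rows, fb.grain_set.rows)
            assert np.array_equal(fa.cost_trace, fb.cost_trace)
        # frame order must not matter: fitting a sub-stack reproduces frame 2
        sub = fit_stack(frames[2:], small_psf, small_cfg, FitConfig(seed=11), 1)
        assert sub[0].grain_set.frame_index == 0  # re-indexed sub-stack

    def test_empty_stack_gives_empty_list(self, small_cfg, small_psf):
        out = fit_stack(np.zeros((0, 16, 16)), small_psf, small_cfg,
                        FitConfig(), 1)
        assert out == []

    def test_final_costs_never_exceed_initial(self, small_cfg, small_psf, rng):
        frames = np.clip(rng.normal(0.2, 0.5, (4, 40, 40)), 0, None)
        for res in fit_stack(frames, small_psf, small_cfg, FitConfig(seed=0),
                             8):
            assert res.cost_trace[-1] <= res.cost_trace[0]

    def test_grains_stay_inside_dilated_support(self, small_cfg, small_psf):
        rng = np.random.default_rng(9)
        sigma_s = grain_sigma_px(small_cfg, FitConfig())
        truth = gs([4.0, 3.0], [14.0, 34.0], [30.0, 18.0], sigma_s)
        hm = np.clip(render_guess(truth, small_psf, (48, 48))
                     + rng.normal(0, 0.02, (48, 48)), 0, None)
        res = fit_frame(hm, small_psf, small_cfg, FitConfig(seed=3), k_start=6)
        sigma_c = np.hypot(sigma_s, small_psf.sigma_px)
        support = binary_dilation(hm > 0.05 * hm.max(),
                                  iterations=int(np.ceil(2 * sigma_c)))
        for r, c in zip(res.grain_set.rows, res.grain_set.cols):
            assert support[int(round(r)), int(round(c))]
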