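import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from sai import (NoiseModel, estimate_signal_area, high_intensity_frames,
                 initial_grain_count, mean_frame, simulate_embedded_speckle)
from sai.extract import MeanFrame


class TestMeanFrame:
    def test_identical_frames(self, rng):
        f = rng.random((8, 8))
        stack = np.stack([f, f, f])
        assert np.allclose(mean_frame(stack).values, f)

    def test_two_frames_elementwise_mean(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert np.allclose(mean_frame(np.stack([a, b])).values, (a + b) / 2)

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            mean_frame(rng.random((1, 8, 8)))


class TestHighIntensityFrames:
    def test_hand_case(self):
        m = np.array([[[5.0, 1.0], [2.0, 8.0]]])
        mbar = MeanFrame(values=np.full((2, 2), 3.0))
        hm = high_intensity_frames(m, mbar).frames[0]
        assert np.array_equal(hm, [[2.0, 0.0], [0.0, 5.0]])

    def test_frame_equal_to_mean_gives_zero(self, rng):
        f = rng.random((8, 8))
        hm = high_intensity_frames(f[None], MeanFrame(values=f)).frames
        assert not np.any(hm)

    def test_frame_below_mean_gives_zero(self, rng):
        f = rng.random((8, 8))
        hm = high_intensity_frames(f[None] * 0.5, MeanFrame(values=f)).frames
        assert not np.any(hm)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            high_intensity_frames(rng.random((2, 8, 8)),
                                  MeanFrame(values=rng.random((9, 9))))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (3, 4, 4),
                      elements=st.floats(0, 100, allow_nan=False)))
    def test_positive_part_oracle(self, frames):
        mbar = mean_frame(frames)
        hm = high_intensity_frames(frames, mbar).frames
        expect = np.where(frames - mbar.values > 0, frames - mbar.values, 0.0)
        assert np.allclose(hm, expect)
        # positive-part contraction: total HM mass below total frame mass
        if frames.sum() > 0:
            assert hm.sum() < frames.sum() + 1e-12

    def test_hig_support_sparser_than_signal(self, small_cfg):
        # on developed speckle the above-average grains are a minority
        pats = np.stack([
            simulate_embedded_speckle(small_cfg, (128, 128), 300, seed=s)
            .intensity for s in range(12)])
        mbar = mean_frame(pats)
        hm = high_intensity_frames(pats, mbar).frames
        frac_hm = np.count_nonzero(hm) / hm.size
        frac_signal = np.count_nonzero(pats > 0.05) / pats.size
        assert frac_hm < 0.5 * frac_signal


class TestSignalArea:
    def test_zero_image(self):
        assert estimate_signal_area(np.zeros((32, 32))).area_px2 == 0

    def test_constructed_area(self):
        img = np.zeros((64, 64))
        img.ravel()[:100] = 50.0
        assert estimate_signal_area(img).area_px2 == 100

    def test_no_clear_background_warns(self):
        img = np.zeros((8, 8))
        img.ravel()[32:] = 100.0     # signal covers half the field
        with pytest.warns(UserWarning):
            estimate_signal_area(img)


class TestSignalAreaOnSimulatedScene:
    def test_area_matches_phantom_truth_support(self, small_cfg, small_psf):
        # A from the noisy mean frame vs the noise-free wide-field support
        # above the same threshold; a dim uniform background (e.g. residual
        # autofluorescence) gives the noise floor a measurable level
        from scipy.signal import fftconvolve

        from sai import FluorophoreMap, NoiseModel, make_filaments, \
            simulate_stack

        fil = make_filaments((96, 96), 2, 240.0, small_cfg.pixel_size_nm,
                             seed=3, n_steps=80)
        rho = FluorophoreMap(density=fil.density + 0.02,
                             pixel_size_nm=fil.pixel_size_nm,
                             truth_features=fil.truth_features)
        stack = simulate_stack(rho, small_cfg, 50,
                               noise=NoiseModel("poisson", photon_scale=100.0),
                               seed=8, psf=small_psf)
        mbar = mean_frame(stack)
        area = estimate_signal_area(mbar)
        widefield = fftconvolve(rho.density, small_psf.values, mode="same")
        truth_area = np.count_nonzero(widefield > area.threshold)
        assert area.threshold > 0.02    # sits above the background level
        assert area.area_px2 == pytest.approx(truth_area, rel=0.15)


class TestInitialGrainCount:
    def test_zero_area(self, small_cfg):
        assert initial_grain_count(0, small_cfg) == 0

    def test_formula_case(self):
        # A=100 px^2, S=2 px -> A_speckle = pi, K = round(100/pi) = 32
        from sai import OpticalConfig
        cfg = OpticalConfig(wavelength_nm=532.0, na_collection=0.25,
                            pixel_size_nm=100.0, speckle_size_nm=200.0)
        assert initial_grain_count(100, cfg) == 32

    def test_proportionality(self, small_cfg):
        k1 = initial_grain_count(400, small_cfg)
        k2 = initial_grain_count(800, small_cfg)
        assert abs(k2 - 2 * k1) <= 1

    def test_negative_area_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            initial_grain_count(-1, small_cfg)
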