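"""Noise-fidelity estimators: recovery of injected noise parameters."""

import numpy as np
import pytest

from lgenoise import fidelity, phantom
from lgenoise.fidelity import RadialPSD, SupportError


@pytest.fixture(scope="module")
def annulus_roi(default_mask):
    return default_mask > 0


class TestHighpass:
    def test_constant_image_zero_residual(self):
        res = fidelity.highpass_residual(np.full((64, 64), 0.3))
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_residual_mean_near_zero(self):
        rng = np.random.default_rng(0)
        img = rng.random((128, 128))
        res = fidelity.highpass_residual(img)
        assert abs(res.mean()) < 1e-3 * res.std()

    def test_low_frequency_sinusoid_suppressed(self):
        x = np.arange(128)
        img = np.sin(2 * np.pi * x / 80)[None, :] * np.ones((128, 1))
        res = fidelity.highpass_residual(img)
        assert (res**2).mean() < 0.1 * (img**2).mean()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            fidelity.highpass_residual(np.zeros((8, 8)), sigma_hp=0)


class TestWaveletMAD:
    @pytest.mark.parametrize("sigma0", [0.004, 0.008, 0.016])
    def test_recovers_injected_gaussian_sigma(self, clean_image, default_mask, sigma0):
        tissue = fidelity.extra_myocardial_tissue_mask(default_mask)
        img = phantom.add_noise(clean_image, phantom.NoiseModel("gaussian", sigma0=sigma0), 1)
        sh = fidelity.estimate_sigma_wavelet_mad(img, tissue)
        assert abs(sh - sigma0) / sigma0 < 0.10

    def test_noiseless_interior_near_zero(self, clean_image, default_mask):
        tissue = fidelity.extra_myocardial_tissue_mask(default_mask)
        assert fidelity.estimate_sigma_wavelet_mad(clean_image, tissue) < 1e-6

    def test_linearity_in_sigma(self, clean_image, default_mask):
        tissue = fidelity.extra_myocardial_tissue_mask(default_mask)
        a = fidelity.estimate_sigma_wavelet_mad(
            phantom.add_noise(clean_image, phantom.NoiseModel("gaussian", sigma0=0.005), 2), tissue
        )
        b = fidelity.estimate_sigma_wavelet_mad(
            phantom.add_noise(clean_image, phantom.NoiseModel("gaussian", sigma0=0.010), 2), tissue
        )
        assert abs(b / a - 2.0) < 0.2

    def test_small_mask_rejected(self):
        mask = np.zeros((64, 64), bool)
        mask[2:6, 2:6] = True
        with pytest.raises(SupportError):
            fidelity.estimate_sigma_wavelet_mad(np.zeros((64, 64)), mask)


class TestRadialPSD:
    def test_white_noise_flat_spectrum(self, annulus_roi):
        rng = np.random.default_rng(0)
        noise = 0.008 * rng.standard_normal(annulus_roi.shape)
        psd = fidelity.radial_psd_masked(noise, annulus_roi)
        band = psd.freqs >= 0.03
        assert psd.power[band].min() > 0
        assert psd.power[band].max() / psd.power[band].min() < 3.0

    def test_amplitude_scaling_quadratic(self, annulus_roi):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal(annulus_roi.shape)
        p1 = fidelity.radial_psd_masked(noise, annulus_roi)
        p2 = fidelity.radial_psd_masked(2.0 * noise, annulus_roi)
        np.testing.assert_allclose(p2.power, 4.0 * p1.power, rtol=1e-9)

    def test_full_frame_matches_periodogram_radial_average(self):
        rng = np.random.default_rng(2)
        wn = rng.standard_normal((128, 128))
        psd = fidelity.radial_psd_masked(wn, np.ones((128, 128), bool))
        # unmasked oracle: periodogram radially averaged on the same bins
        F = np.abs(np.fft.fft2(wn)) ** 2 / wn.size
        fy = np.fft.fftfreq(128)[:, None]
        fx = np.fft.fftfreq(128)[None, :]
        idx = np.floor(np.hypot(fy, fx) * 128).astype(int)
        sel = idx < psd.n_bins
        per = np.bincount(idx[sel], weights=F[sel], minlength=psd.n_bins) / np.bincount(
            idx[sel], minlength=psd.n_bins
        )
        ratio = psd.power / per
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_tiny_roi_rejected(self):
        mask = np.zeros((64, 64), bool)
        mask[3, 3] = True
        with pytest.raises(SupportError):
            fidelity.radial_psd_masked(np.zeros((64, 64)), mask)


class TestLogPSDDistance:
    def test_identity_and_order_of_magnitude(self):
        f = np.linspace(0.05, 0.5, 20)
        p = RadialPSD(f, np.full(20, 2.0))
        assert fidelity.log_psd_distance(p, p) == 0.0
        p10 = RadialPSD(f, 20.0 * np.ones(20))
        assert fidelity.log_psd_distance(p10, p) == pytest.approx(1.0)
        p100 = RadialPSD(f, 200.0 * np.ones(20))
        assert fidelity.log_psd_distance(p100, p) == pytest.approx(4.0)

    def test_nonpositive_bins_excluded(self):
        f = np.linspace(0.05, 0.5, 4)
        a = RadialPSD(f, np.array([1.0, -1.0, 10.0, 1.0]))
        b = RadialPSD(f, np.ones(4))
        # only bins 0, 2, 3 contribute: (0 + 1 + 0)/3
        assert fidelity.log_psd_distance(a, b) == pytest.approx(1 / 3)


class TestSigmaMuSlope:
    @staticmethod
    def _two_level(seed, slope_k, sigma0=0.008):
        img = np.full((128, 128), 0.11)
        img[:, 64:] = 0.35
        labels = np.ones((128, 128), int)
        labels[:, 64:] = 2
        model = phantom.NoiseModel("signal_dependent", sigma0=sigma0, slope_k=slope_k)
        return phantom.add_noise(img, model, seed), labels

    def test_constant_sigma_slope_near_zero(self):
        noisy, labels = self._two_level(5, 0.0)
        b, n = fidelity.sigma_mu_slope(noisy, np.ones_like(labels, bool), label_map=labels)
        assert n >= 10
        assert abs(b) < 0.002

    def test_recovers_injected_slope(self):
        noisy, labels = self._two_level(6, 0.0085)
        b, _ = fidelity.sigma_mu_slope(noisy, np.ones_like(labels, bool), label_map=labels)
        assert abs(b - 0.0085) / 0.0085 < 0.25

    def test_slope_ordering_preserved(self):
        # shallow < medium < steep recovered in order across seeds
        hits = 0
        for seed in range(10):
            est = []
            for k in (0.002, 0.006, 0.012):
                noisy, labels = self._two_level(100 + seed, k)
                b, _ = fidelity.sigma_mu_slope(noisy, np.ones_like(labels, bool), label_map=labels)
                est.append(b)
            hits += est[0] < est[1] < est[2]
        assert hits >= 9

    def test_too_few_windows_rejected(self):
        mask = np.zeros((64, 64), bool)
        mask[:7, :14] = True  # two windows only
        with pytest.raises(SupportError):
            fidelity.sigma_mu_slope(np.random.default_rng(0).random((64, 64)), mask)


class TestShortRangeCorrelation:
    def test_perfectly_correlated_field(self, annulus_roi):
        assert fidelity.short_range_correlation(np.ones(annulus_roi.shape), annulus_roi) == pytest.approx(10.0)

    def test_white_noise_near_half(self, annulus_roi):
        rng = np.random.default_rng(3)
        val = fidelity.short_range_correlation(rng.standard_normal(annulus_roi.shape), annulus_roi)
        assert abs(val - 0.5) < 0.1

    def test_monotone_in_correlation_kernel(self, annulus_roi):
        rng = np.random.default_rng(4)
        vals = []
        for cs in (0.0, 1.0, 2.0, 4.0):
            white = rng.standard_normal(annulus_roi.shape)
            f = phantom._correlate_unit(white, cs) if cs > 0 else white
            vals.append(fidelity.short_range_correlation(f, annulus_roi))
        assert vals == sorted(vals)

    def test_insufficient_overlap_rejected(self):
        mask = np.zeros((64, 64), bool)
        mask[30:32, 30:38] = True  # supports small lags only
        with pytest.raises(SupportError):
            fidelity.short_range_correlation(np.random.default_rng(0).standard_normal((64, 64)), mask)


class TestHighpassMoments:
    def test_gaussian_near_zero_excess_kurtosis(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((64, 64))
        k, s = fidelity.highpass_moments(vals, np.ones((64, 64), bool))
        assert abs(k) < 0.3
        assert abs(s) < 0.2

    def test_laplace_kurtosis_near_three(self):
        rng = np.random.default_rng(6)
        vals = rng.laplace(size=(128, 128))
        k, _ = fidelity.highpass_moments(vals, np.ones((128, 128), bool))
        assert abs(k - 3.0) < 0.5

    def test_small_roi_rejected(self):
        with pytest.raises(SupportError):
            fidelity.highpass_moments(np.zeros((8, 8)), np.ones((8, 8), bool))


class TestMeanRoiIntensity:
    def test_clean_phantom_level(self, clean_image, default_mask):
        assert fidelity.mean_roi_intensity(clean_image, default_mask == 1) == pytest.approx(0.11)

    def test_linearity_under_constant_shift(self, clean_image, default_mask):
        roi = default_mask > 0
        a = fidelity.mean_roi_intensity(clean_image, roi)
        b = fidelity.mean_roi_intensity(clean_image + 0.05, roi)
        assert b - a == pytest.approx(0.05)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            fidelity.mean_roi_intensity(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestEvaluateSets:
    def test_identical_sets_give_zero_paired_differences(self, paired_sources_small):
        real = paired_sources_small["REAL"][:6]
        df, _ = fidelity.evaluate_sets(real, {"COPY": real})
        wide = df.pivot_table(index=["patient_id", "slice_index"], columns="source",
                              values="psd_distance")
        np.testing.assert_allclose(wide["COPY"], wide["REAL"])

    def test_order_invariance(self, paired_sources_small):
        real = paired_sources_small["REAL"][:6]
        dm = paired_sources_small["DM"][:6]
        df1, _ = fidelity.evaluate_sets(real, {"DM": dm})
        df2, _ = fidelity.evaluate_sets(real[::-1], {"DM": dm[::-1]})
        m1 = df1.sort_values(["patient_id", "slice_index", "source"]).reset_index(drop=True)
        m2 = df2.sort_values(["patient_id", "slice_index", "source"]).reset_index(drop=True)
        np.testing.assert_allclose(
            m1["psd_distance"].to_numpy(), m2["psd_distance"].to_numpy()
        )

    def test_dm_like_beats_gan_like_on_psd_distance(self, paired_sources_small):
        srcs = dict(paired_sources_small)
        real = srcs.pop("REAL")
        df, _ = fidelity.evaluate_sets(real, srcs)
        med = df.groupby("source")["psd_distance"].median()
        assert med["DM"] < med["GAN"]

    def test_small_scars_excluded_from_scar_roi(self, paired_sources_small):
        real = list(paired_sources_small["REAL"][:4])
        # shrink one slice's scar below threshold
        sp = real[0]
        mask = sp.mask.copy()
        scar = np.argwhere(mask == 2)
        mask[tuple(scar[60:].T)] = 1  # keep only 60 scar px
        real[0] = phantom.SlicePair(sp.image, mask, sp.patient_id, sp.slice_index)
        df, exc = fidelity.evaluate_sets(real, {}, roi="scar", roi_margin_px=2)
        assert exc["scar_below_threshold"] == 1
        assert len(df) == 3

    def test_unpaired_slices_rejected(self, paired_sources_small):
        real = paired_sources_small["REAL"][:3]
        stray = paired_sources_small["DM"][3:5]
        with pytest.raises(ValueError):
            fidelity.evaluate_sets(real, {"DM": stray})
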