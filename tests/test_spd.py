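import numpy as np
import pytest

from dcm_phenolink.spd import (
    ROI_PX,
    RadialProfile1D,
    SarcomereImage,
    SPDModelParams,
    analyze_image,
    compute_power_spectrum,
    fit_spd_model,
    sarcomere_metrics,
    spd_model,
    wedge_profile,
)
from dcm_phenolink.synth import ImageSpec, generate_sarcomere_image


def cosine_image(period_px=18, angle_deg=0.0, size=256, pixel_size=0.1):
    y, x = np.mgrid[0:size, 0:size]
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    return SarcomereImage(intensity=1.0 + 0.5 * np.cos(2 * np.pi * u / period_px), pixel_size_um=pixel_size)


class TestPowerSpectrum:
    def test_constant_roi_has_no_power(self):
        img = SarcomereImage(intensity=np.full((256, 256), 3.0), pixel_size_um=0.1)
        spec = compute_power_spectrum(img, roi_origin=(0, 0), window=False)
        assert np.allclose(spec.power, 0.0)

    def test_cosine_grating_peaks_at_reciprocal_period(self):
        img = cosine_image(period_px=18)
        spec = compute_power_spectrum(img, roi_origin=(0, 0), window=False)
        fx, fy = np.meshgrid(spec.fx, spec.fy)
        fr = np.hypot(fx, fy)
        peak = np.unravel_index(np.argmax(spec.power), spec.power.shape)
        expected = (1.0 / 18) / 0.1  # cycles/um
        assert fr[peak] == pytest.approx(expected, rel=0.06)
        # peak lies on the grating normal (the x axis)
        assert abs(fy[peak]) <= abs(spec.fy[1] - spec.fy[0]) + 1e-12

    def test_parseval_without_window(self, rng):
        img = SarcomereImage(intensity=rng.standard_normal((256, 256)), pixel_size_um=0.1)
        spec = compute_power_spectrum(img, roi_origin=(10, 20), window=False)
        roi = img.intensity[10 : 10 + ROI_PX, 20 : 20 + ROI_PX]
        roi = roi - roi.mean()
        n_tot = ROI_PX * ROI_PX
        assert spec.power.sum() == pytest.approx(n_tot * np.sum(roi**2), rel=1e-10)

    def test_roi_out_of_bounds_rejected(self):
        img = SarcomereImage(intensity=np.zeros((256, 256)), pixel_size_um=0.1)
        with pytest.raises(ValueError, match="ROI"):
            compute_power_spectrum(img, roi_origin=(100, 100))

    def test_small_image_rejected(self):
        img = SarcomereImage(intensity=np.zeros((150, 150)), pixel_size_um=0.1)
        with pytest.raises(ValueError, match="200"):
            compute_power_spectrum(img)


class TestWedgeProfile:
    def test_orientation_recovered_within_one_degree(self):
        img = generate_sarcomere_image(ImageSpec(size_px=(256, 256), orientation_deg=30.0, noise_sd=0.05, seed=3))
        profile = wedge_profile(compute_power_spectrum(img))
        assert abs(profile.orientation_deg - 30.0) <= 1.0
        assert not profile.low_confidence

    def test_white_noise_is_flat_and_flagged(self, rng):
        img = SarcomereImage(intensity=rng.standard_normal((256, 256)), pixel_size_um=0.1)
        profile = wedge_profile(compute_power_spectrum(img))
        assert profile.low_confidence
        # flat in expectation: band means agree within a factor of two
        mid = len(profile.f) // 2
        lo, hi = profile.power[5:mid].mean(), profile.power[mid:].mean()
        assert 0.5 < lo / hi < 2.0

    def test_profile_maximum_at_fundamental_frequency(self):
        img = generate_sarcomere_image(ImageSpec(size_px=(256, 256), period_um=1.8, noise_sd=0.0, seed=4))
        profile = wedge_profile(compute_power_spectrum(img))
        in_band = (profile.f > 0.2) & (profile.f < 1.0)
        f_peak = profile.f[in_band][np.argmax(profile.power[in_band])]
        assert f_peak == pytest.approx(1.0 / 1.8, rel=0.05)

    def test_profile_excludes_dc(self):
        img = generate_sarcomere_image(ImageSpec(size_px=(256, 256), seed=5))
        profile = wedge_profile(compute_power_spectrum(img))
        assert np.all(profile.f >= 0.05)


def synth_profile(params, f_max=5.0, df=0.05):
    f = np.arange(df, f_max, df)
    return RadialProfile1D(f=f, power=spd_model(f, params), orientation_deg=0.0)


class TestModelFit:
    def test_exact_recovery_from_noiseless_model(self):
        truth = SPDModelParams(a0=1.0, b0=0.8, a1=0.6, b1=0.004, a2=0.15, b2=0.006, f0=0.5556)
        fitted = fit_spd_model(synth_profile(truth, df=0.02))
        for name in ("a0", "b0", "a1", "b1", "a2", "b2", "f0"):
            assert getattr(fitted, name) == pytest.approx(getattr(truth, name), rel=1e-4), name

    def test_pure_exponential_yields_zero_periodic_power(self):
        truth = SPDModelParams(a0=1.0, b0=0.6, a1=0.0, b1=0.01, a2=0.0, b2=0.01, f0=0.5)
        fitted = fit_spd_model(synth_profile(truth))
        spd = sarcomere_metrics(fitted).SPD
        assert spd < 1e-3
        assert fitted.a1 * np.sqrt(np.pi * fitted.b1) + fitted.a2 * np.sqrt(np.pi * fitted.b2) < 1e-3

    def test_f0_robust_to_multiplicative_noise(self, rng):
        truth = SPDModelParams(a0=1.0, b0=0.8, a1=0.6, b1=0.004, a2=0.15, b2=0.006, f0=0.5556)
        f = np.arange(0.05, 5.0, 0.025)
        clean = spd_model(f, truth)
        for _ in range(10):
            noisy = clean * (1.0 + 0.05 * rng.standard_normal(len(f)))
            profile = RadialProfile1D(f=f, power=np.maximum(noisy, 0), orientation_deg=0.0)
            fitted = fit_spd_model(profile)
            assert fitted.f0 == pytest.approx(truth.f0, rel=0.02)

    def test_short_profile_rejected(self):
        f = np.arange(0.1, 0.5, 0.05)
        with pytest.raises(ValueError, match="30 bins"):
            fit_spd_model(RadialProfile1D(f=f, power=np.ones_like(f), orientation_deg=0.0))


class TestMetrics:
    def test_worked_example_sl_and_spd(self):
        # SL = 1/f0 = 1.80 um; SPD = 0.7*sqrt(0.02*pi) / (1 + 0.7*sqrt(0.02*pi))
        p = SPDModelParams(a0=1.0, b0=1.0, a1=0.5, b1=0.02, a2=0.2, b2=0.02, f0=0.5556)
        m = sarcomere_metrics(p)
        assert m.SL_um == pytest.approx(1.7999, rel=1e-3)
        expected = 0.7 * np.sqrt(0.02 * np.pi) / (1 + 0.7 * np.sqrt(0.02 * np.pi))
        assert m.SPD == pytest.approx(expected, rel=1e-4)
        assert m.SPD == pytest.approx(0.149, abs=0.001)

    def test_limit_cases(self):
        assert sarcomere_metrics(SPDModelParams(1.0, 1.0, 0.0, 0.01, 0.0, 0.01, 0.5)).SPD == 0.0
        assert sarcomere_metrics(SPDModelParams(0.0, 1.0, 0.5, 0.01, 0.0, 0.01, 0.5)).SPD == pytest.approx(1.0)
        with pytest.raises(ValueError, match="undefined"):
            sarcomere_metrics(SPDModelParams(0.0, 1.0, 0.0, 0.01, 0.0, 0.01, 0.5))

    def test_sl_is_exact_reciprocal_of_f0(self):
        p = SPDModelParams(1.0, 1.0, 0.5, 0.02, 0.2, 0.02, 0.625)
        assert sarcomere_metrics(p).SL_um == 1.0 / 0.625


class TestAnalyzeImage:
    def test_sl_recovered_within_five_percent(self):
        img = generate_sarcomere_image(ImageSpec(size_px=(256, 256), period_um=1.8, orientation_deg=65.0, seed=6))
        metrics, qc = analyze_image(img)
        assert metrics.SL_um == pytest.approx(1.8, rel=0.05)
        assert 0.0 <= metrics.SPD <= 1.0

    def test_spd_orders_organized_vs_disorganized(self):
        organized = generate_sarcomere_image(ImageSpec(size_px=(256, 256), organized_fraction=1.0, seed=7))
        disorganized = generate_sarcomere_image(ImageSpec(size_px=(256, 256), organized_fraction=0.0, seed=7))
        spd_org = analyze_image(organized)[0].SPD
        spd_dis = analyze_image(disorganized)[0].SPD
        assert spd_org > spd_dis

    def test_spd_invariant_under_intensity_scaling(self):
        img = generate_sarcomere_image(ImageSpec(size_px=(256, 256), organized_fraction=0.7, seed=8))
        scaled = SarcomereImage(intensity=5.0 * img.intensity, pixel_size_um=img.pixel_size_um)
        m1, _ = analyze_image(img)
        m2, _ = analyze_image(scaled)
        assert m2.SPD == pytest.approx(m1.SPD, abs=1e-6)
        assert m2.SL_um == pytest.approx(m1.SL_um, rel=1e-9)

    def test_sl_invariant_under_rotation(self):
        sls = []
        for angle in (0.0, 45.0, 90.0, 135.0):
            img = generate_sarcomere_image(
                ImageSpec(size_px=(256, 256), period_um=1.8, orientation_deg=angle, noise_sd=0.05, seed=9)
            )
            sls.append(analyze_image(img)[0].SL_um)
        assert (max(sls) - min(sls)) / np.mean(sls) < 0.04

    def test_undersized_image_rejected(self):
        img = SarcomereImage(intensity=np.zeros((150, 256)), pixel_size_um=0.1)
        with pytest.raises(ValueError):
            analyze_image(img)
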