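"""Measurement operations against generator truth and brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from oracles import brute_arosa, brute_mask, brute_mpd, brute_otsu

from dermaquant import imaging
from dermaquant.errors import (
    InsufficientLinesError,
    ParameterError,
    SurfaceNotFoundError,
    ThresholdError,
)
from dermaquant.imaging import (
    analyze_image,
    compute_arosa,
    compute_mpd,
    compute_threshold,
    detect_surface,
    extract_channel,
    measure_sct,
    remove_autofluorescence,
)
from dermaquant.synthgen import GeneratorParams, SectionImage, generate_section_image


def _random_masked(rng, shape=(64, 64)):
    img = rng.integers(0, 255, size=shape).astype(float)
    thr = float(rng.uniform(50, 200))
    return np.where(img > thr, img, 0.0), img, thr


class TestExtractChannel:
    def test_gray_passes_through_unchanged(self, default_image):
        image, _ = default_image
        out = extract_channel(image, "hydrophilic")
        assert out.pixels is image.pixels

    def test_channel_separation_on_pure_green(self):
        rgb = np.zeros((10, 12, 3), dtype=np.uint8)
        rgb[..., 1] = 77
        img = SectionImage(pixels=rgb)
        green = extract_channel(img, "hydrophilic")
        red = extract_channel(img, "lipophilic")
        assert np.all(green.pixels == 77)
        assert np.all(red.pixels == 0)

    def test_rgb_render_metrics_equal_grayscale_render(self):
        params = GeneratorParams()
        gray, truth = generate_section_image(params, 21)
        rgb, _ = generate_section_image(params, 21, rgb_channel="red")
        extracted = extract_channel(rgb, "lipophilic")
        assert np.array_equal(extracted.pixels, gray.pixels)
        surf_g = detect_surface(gray)
        surf_e = detect_surface(extracted)
        assert np.array_equal(surf_g, surf_e)
        thr = imaging.ThresholdResult(value=200.0, method="fixed")
        mg = analyze_image(gray, surf_g, thr)
        me = analyze_image(extracted, surf_e, thr)
        assert mg.arosa_mgv_per_px == me.arosa_mgv_per_px
        assert mg.mpd_um == me.mpd_um

    def test_malformed_shape_rejected(self):
        with pytest.raises(ParameterError):
            extract_channel(SectionImage(pixels=np.zeros((5, 5, 2))), "hydrophilic")


class TestDetectSurface:
    def test_flat_surface_recovered_exactly(self, clean_params):
        params = dataclasses.replace(clean_params, surface_row_mean_px=25.0)
        image, _ = generate_section_image(params, 0)
        surface = detect_surface(image)
        assert np.all(surface == 25)

    def test_all_zero_image_raises(self):
        with pytest.raises(SurfaceNotFoundError):
            detect_surface(SectionImage(pixels=np.zeros((64, 64), dtype=np.uint8)))

    def test_noisy_recovery_within_one_pixel(self):
        errors = []
        for i in range(50):
            image, truth = generate_section_image(
                GeneratorParams(surface_roughness_px=1.0, dye_amount=0.0), 1000 + i
            )
            detected = detect_surface(image)
            errors.append(np.abs(detected - truth.surface_rows).mean())
        assert np.mean(errors) < 1.0


class TestMeasureSct:
    def test_clean_band_thickness_and_af(self, clean_params):
        # 20 px band at 2.84 µm/px -> 56.8 µm; uniform band grey 180 -> AF-SC 180
        params = dataclasses.replace(clean_params, sct_um=56.8)
        image, _ = generate_section_image(params, 0)
        profile = measure_sct(image, detect_surface(image))
        assert profile.sct_um_mean == pytest.approx(56.8)
        assert profile.af_sc_mean == pytest.approx(180.0)
        assert np.all(profile.sct_px == profile.sc_bottom_row_px - profile.surface_row_px)

    def test_recovery_on_low_noise_suite(self):
        rng = np.random.default_rng(0)
        errors = []
        for i in range(25):
            params = GeneratorParams(
                sct_um=float(rng.uniform(10, 40)), dye_amount=0.0,
                hotspot_density=0.0, noise_sd=1.0,
            )
            image, truth = generate_section_image(params, 500 + i)
            profile = measure_sct(image, detect_surface(image))
            errors.append(abs(profile.sct_um_mean - truth.sct_eff_um))
        assert np.mean(errors) < 2.84

    def test_too_few_valid_columns_reports_usable_count(self, clean_params):
        image, _ = generate_section_image(clean_params, 0)
        surface = np.full(image.pixels.shape[1], imaging.MISSING)
        surface[:3] = 10
        with pytest.raises(InsufficientLinesError) as err:
            measure_sct(image, surface, n_lines=10)
        assert err.value.usable == 3

    def test_scale_equivariance(self, clean_params):
        # doubling the pixel scale doubles µm readouts at fixed pixel geometry
        p1 = dataclasses.replace(clean_params, sct_um=28.4)
        p2 = dataclasses.replace(clean_params, sct_um=56.8, scale_um_per_px=5.68)
        im1, _ = generate_section_image(p1, 0)
        im2, _ = generate_section_image(p2, 0)
        assert np.array_equal(im1.pixels, im2.pixels)
        prof1 = measure_sct(im1, detect_surface(im1))
        prof2 = measure_sct(im2, detect_surface(im2))
        assert prof2.sct_um_mean == pytest.approx(2 * prof1.sct_um_mean)


class TestThreshold:
    def test_constant_control_gives_its_value(self):
        img = SectionImage(pixels=np.full((32, 32), 50, dtype=np.uint8))
        res = compute_threshold([img], "control_stats")
        assert res.value == pytest.approx(50.0)

    def test_mean_plus_k_sd(self, rng):
        vals = rng.normal(40, 5, size=(200, 200)).clip(0, 255)
        img = SectionImage(pixels=vals.round().astype(np.uint8))
        res = compute_threshold([img], "control_stats", k=3.0)
        assert res.value == pytest.approx(55.0, abs=1.0)

    def test_empty_control_set_rejected(self):
        with pytest.raises(ThresholdError):
            compute_threshold([], "control_stats")

    def test_otsu_matches_exhaustive_scan_between_modes(self, rng):
        for _ in range(5):
            vals = np.concatenate(
                [rng.normal(40, 6, 2000), rng.normal(200, 10, 2096)]
            ).round().clip(0, 255).astype(np.uint8)
            rng.shuffle(vals)
            img = SectionImage(pixels=vals.reshape(64, 64))
            res = compute_threshold(img, "otsu")
            assert 40 < res.value < 200
            assert res.value == pytest.approx(brute_otsu(vals))

    def test_otsu_constant_image_rejected(self):
        img = SectionImage(pixels=np.full((16, 16), 7, dtype=np.uint8))
        with pytest.raises(ThresholdError):
            compute_threshold(img, "otsu")


class TestMaskArosaMpd:
    def test_threshold_above_max_blanks_image(self, default_image):
        image, _ = default_image
        masked = remove_autofluorescence(image, float(image.pixels.max()))
        assert masked.max() == 0

    def test_threshold_below_min_keeps_image(self, default_image):
        image, _ = default_image
        masked = remove_autofluorescence(image, float(image.pixels.min()) - 1)
        assert np.array_equal(masked, image.pixels.astype(float))

    def test_mask_matches_per_pixel_loop(self, rng):
        for _ in range(3):
            masked, img, thr = _random_masked(rng)
            image = SectionImage(pixels=img)
            assert np.array_equal(remove_autofluorescence(image, thr), brute_mask(img, thr))

    def test_arosa_arithmetic(self):
        img = np.zeros((100, 100))
        img[:5, :100] = 200.0  # 500 pixels of value 200
        assert compute_arosa(img) == pytest.approx(10.0)

    def test_arosa_matches_brute_force(self, rng):
        for _ in range(3):
            masked, _, _ = _random_masked(rng)
            assert compute_arosa(masked) == pytest.approx(brute_arosa(masked))

    def test_mpd_arithmetic_flat_surface(self):
        masked = np.zeros((64, 8))
        surface = np.full(8, 5)
        masked[15, 2] = 100.0  # 10 px deep
        masked[35, 6] = 80.0   # 30 px deep
        mpd, n, flags = compute_mpd(masked, surface, 2.84)
        assert mpd == pytest.approx(20 * 2.84)
        assert n == 2 and not flags

    def test_mpd_empty_mask_flags_no_signal(self):
        mpd, n, flags = compute_mpd(np.zeros((10, 10)), np.full(10, 2), 2.84)
        assert mpd == 0.0 and n == 0 and flags.get("NO_SIGNAL")

    def test_mpd_matches_brute_force_and_skips_missing_columns(self, rng):
        for _ in range(3):
            masked, _, _ = _random_masked(rng)
            surface = rng.integers(0, 20, size=64)
            surface[rng.integers(0, 64, size=5)] = imaging.MISSING
            mpd, _, _ = compute_mpd(masked, surface, 2.84)
            assert mpd == pytest.approx(brute_mpd(masked, surface, 2.84))

    def test_no_signal_invariant_in_metrics(self, clean_params):
        image, _ = generate_section_image(clean_params, 0)
        surface = detect_surface(image)
        thr = imaging.ThresholdResult(value=float(image.pixels.max()), method="fixed")
        m = analyze_image(image, surface, thr)
        assert m.n_signal_px == 0
        assert m.flags.get("NO_SIGNAL")
        assert m.arosa_mgv_per_px == 0.0 and m.mpd_um == 0.0

    def test_arosa_bounded_by_image_maximum(self, default_image):
        image, _ = default_image
        surface = detect_surface(image)
        thr = imaging.ThresholdResult(value=200.0, method="fixed")
        m = analyze_image(image, surface, thr)
        assert 0 < m.arosa_mgv_per_px <= image.pixels.max()

    def test_scale_equivariance_of_mpd_and_arosa(self):
        p1 = GeneratorParams()
        # same pixel geometry at twice the scale: double all µm lengths
        p2 = dataclasses.replace(
            p1, scale_um_per_px=2 * p1.scale_um_per_px,
            sct_um=2 * p1.sct_um, dye_decay_um=2 * p1.dye_decay_um,
        )
        im1, _ = generate_section_image(p1, 77)
        im2, _ = generate_section_image(p2, 77)
        assert np.array_equal(im1.pixels, im2.pixels)
        thr = imaging.ThresholdResult(value=185.0, method="fixed")
        m1 = analyze_image(im1, detect_surface(im1), thr)
        m2 = analyze_image(im2, detect_surface(im2), thr)
        assert m2.mpd_um == pytest.approx(2 * m1.mpd_um)
        assert m2.arosa_mgv_per_px == pytest.approx(m1.arosa_mgv_per_px)
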