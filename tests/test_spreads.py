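"""Spot quantification, within-spread normalization, peak-pair distances."""

import numpy as np
import pytest

from neocent import (
    DotPairProfile,
    PeakPairError,
    SpotROI,
    classify_dot_pattern,
    extract_line_profile,
    normalize_within_spread,
    peak_pair_distance,
    quantify_spot,
    read_image,
    simulate_spread,
    write_image,
    SimulationConfig,
)


def gaussian_image(shape=(40, 40), center=(20, 20), amplitude=1000.0, sigma=2.0, background=0.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -(((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))
    )


class TestQuantifySpot:
    def test_zero_image(self):
        assert quantify_spot(np.zeros((40, 40)), SpotROI(center=(20, 20))) == 0.0

    def test_uniform_image_cancels_exactly(self):
        assert quantify_spot(np.full((40, 40), 37.5), SpotROI(center=(20, 20))) == 0.0

    def test_noiseless_gaussian_within_ten_percent_of_integral(self):
        amplitude, sigma = 1000.0, 2.0
        img = gaussian_image(amplitude=amplitude, sigma=sigma, background=50.0)
        corrected = quantify_spot(img, SpotROI(center=(20, 20)))
        integral = amplitude * 2 * np.pi * sigma**2
        assert corrected == pytest.approx(integral, rel=0.10)

    def test_linear_in_amplitude(self):
        amps = np.array([200.0, 500.0, 1000.0, 2000.0, 5000.0])
        meas = [
            quantify_spot(gaussian_image(amplitude=a, background=50.0), SpotROI(center=(20, 20)))
            for a in amps
        ]
        slope = np.polyfit(amps * 2 * np.pi * 4.0, meas, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_negative_corrected_floored_with_flag(self):
        img = np.full((40, 40), 100.0)
        img[11:29, 15:25] = 10.0  # darker than surround
        q = quantify_spot(img, SpotROI(center=(20, 20)), details=True)
        assert q.corrected == 0.0 and q.floored

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError):
            quantify_spot(np.zeros((20, 20)), SpotROI(center=(2, 2)))

    def test_alternative_background_methods_agree_on_flat_background(self):
        img = gaussian_image(background=80.0)
        results = {
            m: quantify_spot(img, SpotROI(center=(20, 20), background_method=m))
            for m in ("median_frame", "corner_mean", "lower_quartile")
        }
        vals = list(results.values())
        assert max(vals) - min(vals) < 0.05 * max(vals)


class TestNormalizeWithinSpread:
    def test_reference_mean_is_unity(self):
        assert normalize_within_spread(3.0, [2.0, 4.0]) == pytest.approx(1.0)
        assert normalize_within_spread(5.0, [5.0]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = normalize_within_spread(3.0, [2.0, 4.0])
        b = normalize_within_spread(30.0, [20.0, 40.0])
        assert a == pytest.approx(b)

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            normalize_within_spread(1.0, [])
        with pytest.raises(ValueError):
            normalize_within_spread(1.0, [0.0, 0.0])


class TestPeakPairDistance:
    def test_delta_peaks(self):
        y = np.zeros(31)
        y[10] = y[20] = 100.0
        profile = DotPairProfile(samples=y, pixel_size=0.1, min_prominence=10)
        assert peak_pair_distance(profile) == pytest.approx(1.0)

    def test_subpixel_gaussian_pair(self):
        x = np.arange(40, dtype=float)
        y = 1000 * np.exp(-((x - 12.15) ** 2) / 8) + 1000 * np.exp(-((x - 25.45) ** 2) / 8)
        profile = DotPairProfile(samples=y, pixel_size=0.1, min_prominence=100)
        assert peak_pair_distance(profile) / 0.1 == pytest.approx(13.3, abs=0.5)

    def test_integer_pixel_mode(self):
        x = np.arange(40, dtype=float)
        y = 1000 * np.exp(-((x - 12.0) ** 2) / 8) + 1000 * np.exp(-((x - 25.0) ** 2) / 8)
        profile = DotPairProfile(samples=y, pixel_size=1.0, min_prominence=100)
        assert peak_pair_distance(profile, subpixel=False) == 13.0

    def test_monotone_profile_is_an_error(self):
        profile = DotPairProfile(samples=np.arange(20.0), pixel_size=0.1)
        with pytest.raises(PeakPairError):
            peak_pair_distance(profile)

    def test_single_peak_is_an_error(self):
        y = 1000 * np.exp(-((np.arange(30.0) - 15) ** 2) / 8)
        with pytest.raises(PeakPairError, match="dot pair"):
            peak_pair_distance(DotPairProfile(samples=y, pixel_size=0.1, min_prominence=100))


class TestClassifyDotPattern:
    def make(self, separation_px, amplitude=1000.0, n=41):
        x = np.arange(n, dtype=float)
        mid = (n - 1) / 2
        if separation_px == 0:
            y = 2 * amplitude * np.exp(-((x - mid) ** 2) / 8)
        else:
            y = amplitude * (
                np.exp(-((x - mid + separation_px / 2) ** 2) / 8)
                + np.exp(-((x - mid - separation_px / 2) ** 2) / 8)
            )
        return DotPairProfile(samples=y, pixel_size=0.1, min_prominence=100)

    def test_coincident_peaks_are_one_dot(self):
        assert classify_dot_pattern(self.make(0)) == "one-dot"

    def test_well_separated_peaks_are_two_dots(self):
        assert classify_dot_pattern(self.make(6.0), resolution_px=3.0) == "two-dots"

    def test_noise_below_prominence_is_undetermined(self):
        y = np.random.default_rng(0).normal(0, 1, 41)
        assert classify_dot_pattern(DotPairProfile(y, 0.1, min_prominence=50)) == "undetermined"


class TestSpreadImages:
    def test_image_round_trip_text_and_tiff(self, tmp_path, config):
        img, _ = simulate_spread(config, seed=9)
        # tiff is rounded to uint16 with negatives clipped; text keeps 4 decimals
        for name, reference, tol in (
            ("spread.txt", img, 1e-4),
            ("spread.tif", np.clip(img, 0, 65_535), 0.5),
        ):
            write_image(img, tmp_path / name)
            back = read_image(tmp_path / name)
            assert back.shape == img.shape
            assert np.abs(back - reference).max() <= tol

    def test_noiseless_single_spot_integrates_to_planted_amplitude(self):
        cfg = SimulationConfig(
            n_spot_pairs=1, noise_sd=0.0, background_level=0.0, spot_separation=1.0
        )
        img, truth = simulate_spread(cfg, seed=3)
        assert img.sum() == pytest.approx(truth.integrated_amplitude.sum(), rel=0.01)

    def test_pair_separation_unit_conversion(self, config):
        _, truth = simulate_spread(config, seed=4)
        assert (truth.separation_px == 10.0).all()  # 1.0 um at 0.1 um/px
        for _, pair in truth.groupby("pair_id"):
            (r1, c1), (r2, c2) = pair[["row", "col"]].to_numpy()
            assert np.hypot(r2 - r1, c2 - c1) == pytest.approx(10.0)
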