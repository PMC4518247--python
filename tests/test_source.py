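"""Source diagnostics: spectral fit and wire-diffraction source size."""

import numpy as np
import pytest

import betaxct as bx
from betaxct.source import (estimate_source_size, model_wire_profile,
                            reconstruct_spectrum, simulate_filter_measurement)

THICKNESSES = np.array([20, 40, 70, 110, 160, 230, 320, 440, 630], float)


class TestSpectrumFit:
    def test_noiseless_round_trip(self, detector_response):
        meas = simulate_filter_measurement(
            4.9, THICKNESSES, detector_response=detector_response,
            base_filter_um=20.0)
        fit = reconstruct_spectrum(meas, detector_response=detector_response,
                                   base_filter_um=20.0)
        assert fit.E_c_keV == pytest.approx(4.9, rel=0.02)

    def test_noisy_monte_carlo(self, detector_response):
        errors = []
        for s in range(100):
            meas = simulate_filter_measurement(
                4.9, THICKNESSES, detector_response=detector_response,
                base_filter_um=20.0, noise_rms=0.05, seed=2000 + s)
            fit = reconstruct_spectrum(meas,
                                       detector_response=detector_response,
                                       base_filter_um=20.0)
            errors.append(abs(fit.E_c_keV - 4.9) / 4.9)
        assert np.median(errors) < 0.10

    def test_underdetermined_raises(self, detector_response):
        meas = simulate_filter_measurement(4.9, [50.0, 50.0, 50.0],
                                           detector_response=detector_response)
        with pytest.raises(ValueError, match="underdetermined"):
            reconstruct_spectrum(meas, detector_response=detector_response)

    def test_fitted_spectrum_is_filtered(self, detector_response):
        meas = simulate_filter_measurement(
            4.9, THICKNESSES, detector_response=detector_response,
            base_filter_um=20.0)
        fit = reconstruct_spectrum(meas, detector_response=detector_response,
                                   base_filter_um=20.0)
        # behind 20 um Al the 1 keV bin is strongly suppressed
        assert fit.spectrum.weights[0] < 0.01 * fit.spectrum.weights.max()


class TestWireModel:
    def test_quarter_intensity_at_edge_monochromatic(self, wire_arm):
        # evaluated on a fine 2.25 um virtual detector so a sample lands on
        # the geometric edge itself
        mono = bx.Spectrum(np.array([4.99, 5.0, 5.01]),
                           np.array([0.0, 1.0, 0.0]))
        fine_px = 2.25
        n = 1024
        profile = model_wire_profile(0.0, mono, wire_arm,
                                     wire_diameter_um=100.0, n_pixels=n,
                                     detector_pixel_um=fine_px, supersample=8)
        x = (np.arange(n) - (n - 1) / 2) * fine_px
        edge_px = int(np.argmin(np.abs(x - 50.0 * wire_arm.M)))
        assert profile[edge_px] == pytest.approx(0.25, abs=0.05)

    def test_first_overshoot_value_monochromatic(self, wire_arm):
        mono = bx.Spectrum(np.array([4.99, 5.0, 5.01]),
                           np.array([0.0, 1.0, 0.0]))
        profile = model_wire_profile(0.0, mono, wire_arm, n_pixels=256,
                                     supersample=32)
        assert profile.max() == pytest.approx(1.37, abs=0.04)

    def test_overshoot_decreases_with_source_size(self, beam_spectrum,
                                                  wire_arm, detector_response):
        peaks = [model_wire_profile(s, beam_spectrum, wire_arm,
                                    detector_response=detector_response,
                                    n_pixels=160).max()
                 for s in (0.0, 1.0, 1.8, 3.0, 5.0)]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))


class TestSourceSizeEstimate:
    def test_recovers_generated_size(self, beam_spectrum, wire_arm,
                                     detector_response):
        img = bx.simulate_wire_image(1.8, beam_spectrum, wire_arm,
                                     detector_response=detector_response,
                                     n_cols=160, n_rows=48, curvature_px=1.5,
                                     photons_per_pixel=2e3, seed=5)
        fit = estimate_source_size(img, beam_spectrum, wire_arm,
                                   detector_response=detector_response)
        assert fit.sigma_best_um == pytest.approx(1.8, abs=0.1)

    def test_sharp_source_limit(self, beam_spectrum, wire_arm,
                                detector_response):
        grid = np.arange(0.0, 2.01, 0.1)
        profile = model_wire_profile(0.0, beam_spectrum, wire_arm,
                                     detector_response=detector_response,
                                     n_pixels=160)
        image = np.tile(profile, (16, 1))
        fit = estimate_source_size(image, beam_spectrum, wire_arm,
                                   sigma_grid_um=grid,
                                   detector_response=detector_response,
                                   detector_pixel_um=22.5)
        assert fit.sigma_best_um <= 0.1 + 1e-9

    def test_tilt_robustness(self, beam_spectrum, wire_arm, detector_response):
        fits = []
        for tilt in (0.0, 2.0):
            img = bx.simulate_wire_image(1.8, beam_spectrum, wire_arm,
                                         detector_response=detector_response,
                                         n_cols=160, n_rows=48, tilt_deg=tilt)
            fits.append(estimate_source_size(
                img, beam_spectrum, wire_arm,
                detector_response=detector_response).sigma_best_um)
        assert abs(fits[1] - fits[0]) < 0.1

    def test_no_edge_raises(self, beam_spectrum, wire_arm, rng):
        flat = 1.0 + 0.001 * rng.normal(size=(32, 160))
        with pytest.raises(ValueError, match="contrast|edge"):
            estimate_source_size(flat, beam_spectrum, wire_arm)

    def test_misfit_convex_near_minimum(self, beam_spectrum, wire_arm,
                                        detector_response):
        img = bx.simulate_wire_image(1.8, beam_spectrum, wire_arm,
                                     detector_response=detector_response,
                                     n_cols=160, n_rows=16)
        fit = estimate_source_size(img, beam_spectrum, wire_arm,
                                   detector_response=detector_response)
        j = int(np.argmin(fit.misfit))
        assert 0 < j < len(fit.misfit) - 1
        assert fit.misfit[j - 1] > fit.misfit[j] < fit.misfit[j + 1]
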