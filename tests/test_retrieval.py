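"""Single-material TIE retrieval: filter properties, limits, oracle."""

import numpy as np
import pytest

import betaxct as bx
from betaxct.retrieval import (_tie_smooth, effective_constants,
                               paganin_retrieve, projected_density,
                               reference_thickness,
                               retrieve_thickness_polychromatic,
                               thickness_to_phase, tie_filter)


@pytest.fixture(scope="module")
def published_const():
    # the published effective constants of the chitin reconstruction
    return bx.EffectiveConstants(mu_poly=70.15, delta_poly=1.38e-5,
                                 E_mean_keV=8.8,
                                 lambda_mean_A=bx.energy_to_wavelength(8.8))


class TestEffectiveConstants:
    def test_monochromatic_degenerate(self, chitin):
        mono = bx.Spectrum(np.array([7.99, 8.0, 8.01]),
                           np.array([0.0, 1.0, 0.0]))
        c = effective_constants(mono, chitin)
        assert c.mu_poly == pytest.approx(chitin.mu(8.0), rel=1e-9)
        assert c.delta_poly == pytest.approx(chitin.delta(8.0), rel=1e-9)
        assert c.E_mean_keV == pytest.approx(8.0)

    def test_weight_scale_invariance(self, beam_spectrum, chitin,
                                     detector_response):
        a = effective_constants(beam_spectrum, chitin,
                                detector_response=detector_response)
        scaled = bx.Spectrum(beam_spectrum.energies,
                             17.0 * beam_spectrum.weights)
        b = effective_constants(scaled, chitin,
                                detector_response=detector_response)
        assert a.mu_poly == pytest.approx(b.mu_poly, rel=1e-12)
        assert a.E_mean_keV == pytest.approx(b.E_mean_keV, rel=1e-12)

    def test_detector_mean_energy_regression(self, beam_spectrum, chitin,
                                             detector_response):
        # detector weighting hardens the beam: E_mean ends up between the
        # spectral peak and twice the peak
        c = effective_constants(beam_spectrum, chitin,
                                detector_response=detector_response)
        peak = beam_spectrum.peak_energy()
        assert peak < c.E_mean_keV < 2 * peak
        assert c.lambda_mean_A == pytest.approx(
            bx.energy_to_wavelength(c.E_mean_keV))

    def test_transmission_matching_softens_mu(self, beam_spectrum, chitin,
                                              detector_response):
        mean = effective_constants(beam_spectrum, chitin,
                                   detector_response=detector_response)
        matched = effective_constants(beam_spectrum, chitin,
                                      detector_response=detector_response,
                                      method="transmission", t_ref_um=500.0)
        assert matched.mu_poly < mean.mu_poly
        # and it reproduces the actual polychromatic transmission at t_ref
        w = beam_spectrum.weights * detector_response(beam_spectrum.energies)
        w = w / w.sum()
        i_true = w @ np.exp(-chitin.mu(beam_spectrum.energies) * 500e-4)
        assert np.exp(-matched.mu_poly * 500e-4) == pytest.approx(i_true,
                                                                  rel=1e-9)


class TestTieFilter:
    def test_unit_dc_gain_preserves_mean(self, tomo_arm, published_const, rng):
        img = 1.0 + 0.05 * rng.normal(size=(64, 64))
        smoothed, _, _ = _tie_smooth(img, tomo_arm, published_const, 22.5,
                                     pad_factor=1)
        assert smoothed.mean() == pytest.approx(img.mean(), rel=1e-9)
        filt = tie_filter((64, 64), 6.04, tomo_arm, published_const)
        assert filt[0, 0] == 1.0
        assert np.all(filt > 0) and np.all(filt <= 1.0)

    def test_translation_equivariance(self, tomo_arm, published_const, rng):
        from scipy import ndimage
        img = 1.0 - 0.3 * ndimage.gaussian_filter(
            rng.random((64, 64)) > 0.98, 3.0).astype(float)
        t1 = paganin_retrieve(np.roll(img, (5, -7), axis=(0, 1)), tomo_arm,
                              published_const, pad_factor=1).thickness_um
        t2 = np.roll(paganin_retrieve(img, tomo_arm, published_const,
                                      pad_factor=1).thickness_um,
                     (5, -7), axis=(0, 1))
        assert np.allclose(t1, t2, atol=1e-9)

    def test_against_direct_quadrature_oracle(self, tomo_arm, published_const,
                                              rng):
        # brute-force DFT evaluation of the filter on a 32x32 image
        img = 1.0 + 0.1 * rng.normal(size=(32, 32))
        fft_result, _, pixel_s = _tie_smooth(img, tomo_arm, published_const, 22.5,
                                             pad_factor=1)
        n = 32
        ky = 2 * np.pi * np.fft.fftfreq(n, d=pixel_s * 1e-6)
        kx = ky.copy()
        direct = np.zeros((n, n), complex)
        F = np.zeros((n, n), complex)
        grid = np.arange(n)
        for u in range(n):
            for v in range(n):
                phase = np.exp(-2j * np.pi * (u * grid[:, None] +
                                              v * grid[None, :]) / n)
                F[u, v] = (img * phase).sum()
        coeff = (tomo_arm.d / tomo_arm.M) * published_const.delta_poly / (
            published_const.mu_poly * 1e2)
        for y in range(n):
            for x in range(n):
                phase = np.exp(2j * np.pi * (grid[:, None] * y +
                                             grid[None, :] * x) / n)
                filt = 1.0 / (1.0 + coeff * (ky[:, None] ** 2 +
                                             kx[None, :] ** 2))
                direct[y, x] = (F * filt * phase).sum() / n ** 2
        assert np.sqrt(np.mean((fft_result - direct.real) ** 2)) < 1e-9


class TestRetrievalLimits:
    def test_contact_limit_exact(self, published_const):
        g = bx.make_geometry(0.73, 0.0)
        T = np.zeros((32, 32))
        T[8:24, 8:24] = 40.0
        I = np.exp(-published_const.mu_poly * T * 1e-4)
        out = paganin_retrieve(I, g, published_const, pad_factor=1)
        assert np.allclose(out.thickness_um, T, atol=1e-9)

    def test_uniform_flat_gives_zero(self, tomo_arm, published_const):
        out = paganin_retrieve(np.ones((32, 32)), tomo_arm, published_const)
        assert np.allclose(out.thickness_um, 0.0, atol=1e-9)

    def test_nonpositive_intensity_clipped_and_counted(self, published_const):
        # contact geometry: the filter is the identity, so the injected
        # non-positive block reaches the log stage unchanged
        contact = bx.make_geometry(0.73, 0.0)
        img = np.ones((32, 32))
        img[10:12, 10:12] = -0.5
        out = paganin_retrieve(img, contact, published_const, pad_factor=1)
        assert out.clipped_pixels > 0
        assert np.all(np.isfinite(out.thickness_um))


class TestPhaseAndDensity:
    def test_phase_hand_value(self, published_const):
        # delta=1.38e-5, lambda=1.4 A, T=10 um:
        # phi = -2*pi*1.38e-5*1e-5 m / 1.4e-10 m = -6.19 rad
        tmap = bx.ThicknessMap(np.full((4, 4), 10.0), 6.0)
        const = bx.EffectiveConstants(70.15, 1.38e-5, 8.8557, 1.4)
        phi = thickness_to_phase(tmap, const)
        assert phi[0, 0] == pytest.approx(-6.193, rel=1e-3)

    def test_phase_linear_in_thickness(self, published_const):
        t1 = bx.ThicknessMap(np.full((2, 2), 5.0), 6.0)
        t2 = bx.ThicknessMap(np.full((2, 2), 10.0), 6.0)
        assert thickness_to_phase(t2, published_const)[0, 0] == pytest.approx(
            2 * thickness_to_phase(t1, published_const)[0, 0], rel=1e-12)
        assert thickness_to_phase(
            bx.ThicknessMap(np.zeros((2, 2)), 6.0), published_const)[0, 0] == 0.0

    def test_areal_density_round_trip(self, chitin):
        lam = bx.energy_to_wavelength(8.8)
        const = bx.EffectiveConstants(15.0, chitin.delta(8.8), 8.8, lam)
        tmap = bx.ThicknessMap(np.full((2, 2), 100.0), 6.0)
        areal = projected_density(tmap, chitin, const)
        assert areal[0, 0] == pytest.approx(100e-4 * chitin.n_e, rel=1e-6)


class TestPolychromaticInversion:
    def test_matches_log_for_monochromatic(self, tomo_arm, chitin):
        mono = bx.Spectrum(np.array([7.99, 8.0, 8.01]),
                           np.array([0.0, 1.0, 0.0]))
        const = effective_constants(mono, chitin)
        T = np.zeros((32, 32))
        T[8:24, 8:24] = 60.0
        g0 = bx.make_geometry(0.73, 0.0)
        I = np.exp(-const.mu_poly * T * 1e-4)
        a = paganin_retrieve(I, g0, const, pad_factor=1).thickness_um
        b = retrieve_thickness_polychromatic(I, g0, mono, chitin, const=const,
                                             pad_factor=1).thickness_um
        assert np.allclose(a, b, atol=0.05)

    def test_unbiased_across_depths(self, beam_spectrum, chitin,
                                    detector_response):
        # a thickness staircase in contact geometry: the LUT inversion must
        # recover every step, where a single mu_poly cannot
        g0 = bx.make_geometry(0.73, 0.0)
        steps = np.array([50.0, 200.0, 500.0, 900.0])
        T = np.repeat(steps, 8).reshape(4, 8).repeat(8, axis=0).T
        T = np.tile(T, (2, 1))[:32, :32]
        w = beam_spectrum.weights * detector_response(beam_spectrum.energies)
        w = w / w.sum()
        I = (np.exp(-np.multiply.outer(T * 1e-4,
                                       chitin.mu(beam_spectrum.energies))) @ w)
        out = retrieve_thickness_polychromatic(
            I, g0, beam_spectrum, chitin, detector_response=detector_response,
            const=effective_constants(beam_spectrum, chitin,
                                      detector_response=detector_response,
                                      method="transmission", t_ref_um=500.0),
            pad_factor=1)
        assert np.allclose(out.thickness_um, T, rtol=1e-3, atol=0.5)

    def test_reference_thickness_fixed_point(self, beam_spectrum, chitin,
                                             detector_response):
        w = beam_spectrum.weights * detector_response(beam_spectrum.energies)
        w = w / w.sum()
        t_true = 400.0
        i_min = float(w @ np.exp(-chitin.mu(beam_spectrum.energies)
                                 * t_true * 1e-4))
        img = np.full((64, 64), 1.0)
        img[24:40, 24:40] = i_min
        t_est = reference_thickness(img, beam_spectrum, chitin,
                                    detector_response=detector_response,
                                    smooth_sigma=0.1)
        assert t_est == pytest.approx(t_true, rel=0.02)
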