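"""Polychromatic radiographs and noisy tilt-series acquisition."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import betaxct as bx


@pytest.fixture(scope="module")
def small_phantom():
    chi = bx.chitin()
    g = bx.make_geometry(0.73, 0.26)
    pixel_s = g.sample_plane_pixel(22.5)
    return bx.make_phantom("insect_like", (32, 32, 32), pixel_s, chi), g


class TestRadiograph:
    def test_flat_field_identity(self, beam_spectrum, tomo_arm, chitin,
                                 detector_response):
        T = np.zeros((64, 64))
        I = bx.radiograph_from_thickness(T, beam_spectrum, tomo_arm, chitin,
                                         detector_response=detector_response)
        assert np.allclose(I, 1.0, atol=1e-9)

    def test_contact_limit_is_beer_lambert(self, beam_spectrum, chitin,
                                           detector_response):
        g = bx.make_geometry(0.73, 0.0)
        T = np.full((32, 32), 50.0)
        T[:, :16] = 0.0
        I = bx.radiograph_from_thickness(T, beam_spectrum, g, chitin,
                                         detector_response=detector_response,
                                         supersample=1)
        w = beam_spectrum.weights * detector_response(beam_spectrum.energies)
        w = w / w.sum()
        expected = w @ np.exp(-np.outer(chitin.mu(beam_spectrum.energies),
                                        np.array([0.0, 50e-4])))
        assert I[0, 0] == pytest.approx(expected[0], rel=1e-3)
        assert I[0, -1] == pytest.approx(expected[1], rel=1e-3)

    def test_fringe_visibility_decreases_with_source_size(
            self, beam_spectrum, tomo_arm, chitin, detector_response):
        n = 128
        ps = tomo_arm.sample_plane_pixel(22.5)
        x = (np.arange(n) - (n - 1) / 2) * ps
        T = np.tile(bx.cylinder_chord(x, 150.0), (n, 1))
        vis = []
        for sigma in (0.0, 1.8, 5.0):
            I = bx.radiograph_from_thickness(
                T, beam_spectrum, tomo_arm, chitin, source_sigma_um=sigma,
                detector_response=detector_response)
            edge = I[n // 2, :]
            vis.append((edge.max() - edge.min()) / (edge.max() + edge.min()))
        assert vis[0] > vis[1] > vis[2]

    def test_missing_optics_range_raises(self, tomo_arm, chitin):
        bad = bx.Spectrum(np.array([0.3, 0.5]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="keV"):
            bx.radiograph_from_thickness(np.zeros((16, 16)), bad, tomo_arm,
                                         chitin)


class TestTiltSeries:
    def test_protocol_shot_count(self, small_phantom, beam_spectrum):
        ph, g = small_phantom
        series = bx.acquire_tilt_series(ph, beam_spectrum, g, n_projections=6,
                                        shots_per_projection=4,
                                        photons_per_shot=1e5, seed=7)
        assert len(series) == 24
        angles = series.angles_deg
        assert np.allclose(np.unique(angles), np.arange(6) * 60.0)

    def test_seeded_determinism(self, small_phantom, beam_spectrum):
        ph, g = small_phantom
        kw = dict(n_projections=3, shots_per_projection=2,
                  photons_per_shot=1e5, seed=99)
        a = bx.acquire_tilt_series(ph, beam_spectrum, g, **kw)
        b = bx.acquire_tilt_series(ph, beam_spectrum, g, **kw)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
        assert all(x.true_shift_um == y.true_shift_um for x, y in zip(a, b))

    def test_seed_mandatory(self, small_phantom, beam_spectrum):
        ph, g = small_phantom
        with pytest.raises(ValueError, match="seed"):
            bx.acquire_tilt_series(ph, beam_spectrum, g, n_projections=2,
                                   shots_per_projection=1, seed=None)

    def test_flux_factor_statistics(self):
        # truncated Gaussian at sigma/mu = 0.20: over many draws the r.m.s.
        # matches and the fraction above 10/16 of the mean sits at the
        # distribution's own value (~0.97)
        dist = truncnorm(-5.0, np.inf, loc=1.0, scale=0.20)
        draws = dist.rvs(size=10000, random_state=np.random.default_rng(1))
        assert np.std(draws) == pytest.approx(0.20, abs=0.01)
        assert np.mean(draws > 0.625) == pytest.approx(0.97, abs=0.01)

    def test_jitter_moves_image_as_recorded(self, small_phantom,
                                            beam_spectrum):
        ph, g = small_phantom
        series = bx.acquire_tilt_series(ph, beam_spectrum, g, n_projections=1,
                                        shots_per_projection=8,
                                        jitter_v_um=0.0, jitter_h_um=30.0,
                                        flux_rms=1e-9, photons_per_shot=1e9,
                                        source_sigma_um=0.0, seed=21)
        from betaxct.preprocess import register
        ref = series[0]
        for shot in list(series)[1:3]:
            res = register(shot.pixels / shot.flat_reference,
                           ref.pixels / ref.flat_reference, search_radius=8)
            expected_dx = ((shot.true_shift_um[1] - ref.true_shift_um[1])
                           * (g.M - 1.0) / 22.5)
            assert res.shift[1] == pytest.approx(expected_dx, abs=0.1)

    def test_io_round_trip(self, tmp_path, small_phantom, beam_spectrum):
        import betaxct.io as bio
        ph, g = small_phantom
        series = bx.acquire_tilt_series(ph, beam_spectrum, g, n_projections=2,
                                        shots_per_projection=2,
                                        photons_per_shot=1e4, seed=5)
        path = tmp_path / "series.h5"
        bio.save_tilt_series(path, series)
        loaded = bio.load_tilt_series(path)
        assert len(loaded) == len(series)
        assert np.array_equal(loaded[3].pixels, series[3].pixels)
        assert loaded[3].true_shift_um == pytest.approx(series[3].true_shift_um)
        assert loaded.geometry.M == pytest.approx(g.M)

    def test_tiff_export(self, tmp_path, small_phantom, beam_spectrum):
        import betaxct.io as bio
        ph, g = small_phantom
        series = bx.acquire_tilt_series(ph, beam_spectrum, g, n_projections=1,
                                        shots_per_projection=2,
                                        photons_per_shot=1e4, seed=5)
        paths = bio.save_tiff_stack(tmp_path, series)
        assert len(paths) == 2
        import tifffile
        assert tifffile.imread(paths[0]).shape == (32, 32)
        assert (tmp_path / "shot_metadata.csv").exists()
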