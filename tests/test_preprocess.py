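"""Raw-image treatment: registration, background, averaging, alignment."""

import numpy as np
import pytest

import betaxct as bx
from betaxct.preprocess import (align_tomography_axis, average_and_bin,
                                background_correct, fourier_shift, register)


def smooth_blobs(rng, n=96, k=12, sigma=3.0):
    from scipy import ndimage
    img = np.zeros((n, n))
    ys, xs = rng.integers(12, n - 12, (2, k))
    img[ys, xs] = rng.uniform(1, 3, k)
    return ndimage.gaussian_filter(img, sigma)


def bandlimited_image(rng, n=96, fmax=0.15):
    """Strictly band-limited random image: exact under Fourier translation."""
    spec = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    spec[np.sqrt(fy ** 2 + fx ** 2) > fmax] = 0.0
    return np.real(np.fft.ifft2(spec))


class TestFourierShift:
    def test_zero_shift_is_identity(self, rng):
        img = rng.normal(size=(32, 32))
        assert np.array_equal(fourier_shift(img, (0, 0)), img)

    def test_invertibility(self, rng):
        img = bandlimited_image(rng)
        back = fourier_shift(fourier_shift(img, (0.37, -1.21)), (-0.37, 1.21))
        assert np.sqrt(np.mean((back - img) ** 2)) < 1e-9 * np.std(img)

    def test_integer_shift_equals_roll(self, rng):
        img = rng.normal(size=(32, 32))
        shifted = fourier_shift(img, (3, -2))
        assert np.allclose(shifted, np.roll(img, (3, -2), axis=(0, 1)),
                           atol=1e-9)

    def test_intensity_conserved(self, rng):
        img = smooth_blobs(rng)
        assert fourier_shift(img, (0.5, 0.5)).sum() == pytest.approx(
            img.sum(), rel=1e-9)


class TestRegister:
    def test_self_registration(self, rng):
        img = smooth_blobs(rng)
        res = register(img, img)
        assert res.shift[0] == pytest.approx(0.0, abs=1e-9)
        assert res.shift[1] == pytest.approx(0.0, abs=1e-9)
        assert res.peak_ncc == pytest.approx(1.0, abs=1e-6)

    def test_integer_shift_exact(self, rng):
        img = smooth_blobs(rng)
        res = register(np.roll(img, (3, -2), axis=(0, 1)), img,
                       search_radius=6, apodize=False)
        assert (round(res.shift[0]), round(res.shift[1])) == (3, -2)

    def test_subpixel_accuracy(self, rng):
        img = smooth_blobs(rng)
        res = register(fourier_shift(img, (0.30, -0.60)), img)
        assert res.shift[0] == pytest.approx(0.30, abs=0.05)
        assert res.shift[1] == pytest.approx(-0.60, abs=0.05)

    def test_many_random_subpixel_shifts(self, rng):
        img = smooth_blobs(rng)
        errs = []
        for _ in range(100):
            dy, dx = rng.uniform(-2, 2, 2)
            res = register(fourier_shift(img, (dy, dx)), img)
            errs.append(np.hypot(res.shift[0] - dy, res.shift[1] - dx))
        assert np.max(errs) <= 0.05

    def test_constant_image_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            register(np.ones((16, 16)), rng.normal(size=(16, 16)))


class TestBackgroundCorrect:
    def _quadratic(self, n=96):
        y = np.linspace(-1, 1, n)
        x = np.linspace(-1, 1, n)
        yy, xx = np.meshgrid(y, x, indexing="ij")
        return 5.0 + 2.0 * yy - 1.0 * xx + 0.8 * yy * xx + 1.5 * yy ** 2 \
            - 0.7 * xx ** 2

    def test_pure_quadratic_removed_exactly(self):
        img = self._quadratic()
        out = background_correct(img, mask=np.zeros_like(img, bool))
        assert np.std(out) < 1e-9 * np.std(img)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-9)

    def test_disc_on_quadratic_background(self):
        img = self._quadratic()
        yy, xx = np.meshgrid(*[np.arange(96) - 48] * 2, indexing="ij")
        disc = np.sqrt(yy ** 2 + xx ** 2) < 15
        img2 = img + 3.0 * disc
        out = background_correct(img2)
        bg_var_before = np.std(img[~disc])
        bg_var_after = np.std(out[~disc])
        assert bg_var_after < 0.01 * bg_var_before
        # the object's excess over the flattened background is untouched
        inner = np.sqrt(yy ** 2 + xx ** 2) < 10
        excess = out[inner].mean() - out[~disc].mean()
        assert excess == pytest.approx(3.0, rel=0.005)

    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 3.3)
        assert np.allclose(background_correct(img), img, atol=1e-12)

    def test_oversized_mask_rejected(self, rng):
        img = rng.normal(size=(32, 32))
        with pytest.raises(ValueError, match="background region"):
            background_correct(img, mask=np.ones_like(img, bool))

    def test_divide_mode_normalises_to_one(self):
        img = self._quadratic()
        out = background_correct(img, mask=np.zeros_like(img, bool),
                                 mode="divide")
        assert np.allclose(out, 1.0, atol=1e-9)


class TestAverageAndBin:
    def test_shapes_follow_protocol(self, rng):
        stack = rng.normal(size=(24, 32, 32))  # 6 angles x 4 shots
        out = average_and_bin(stack, shots_per=4, bin_factor=2)
        assert out.shape == (6, 16, 16)

    def test_identical_shots_average_to_themselves(self, rng):
        img = rng.normal(size=(16, 16))
        out = average_and_bin(np.stack([img] * 4), shots_per=4, bin_factor=1)
        assert np.allclose(out[0], img, atol=1e-12)

    def test_mean_intensity_conserved(self, rng):
        stack = rng.normal(size=(8, 32, 32)) + 5.0
        out = average_and_bin(stack, shots_per=2, bin_factor=2)
        assert out.mean() == pytest.approx(stack.mean(), rel=1e-9)

    def test_poisson_variance_quartered_by_four_shots(self):
        rng = np.random.default_rng(7)
        lam = 100.0
        var1, var4 = [], []
        for _ in range(100):
            shots = rng.poisson(lam, size=(4, 16, 16)).astype(float)
            var1.append(shots[0].var())
            var4.append(shots.mean(axis=0).var())
        assert np.mean(var4) == pytest.approx(np.mean(var1) / 4, rel=0.1)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            average_and_bin(rng.normal(size=(7, 16, 16)), shots_per=4)


class TestAxisAlignment:
    def test_round_trip_recovery(self, rng):
        base = smooth_blobs(rng, n=64)
        offsets = rng.uniform(-3, 3, 12)
        stack = np.stack([fourier_shift(base, (dz, 0.0)) for dz in offsets])
        aligned, measured = align_tomography_axis(stack)
        # measured offsets match the injected ones up to a common constant
        resid = (measured - offsets) - np.median(measured - offsets)
        assert np.abs(resid).max() < 0.1

    def test_aligned_stack_is_fixed_point(self, rng):
        base = smooth_blobs(rng, n=64)
        stack = np.stack([base] * 5)
        _, offsets = align_tomography_axis(stack)
        assert np.abs(offsets).max() < 0.05

    def test_horizontal_constant_passes_through(self, rng):
        base = smooth_blobs(rng, n=64)
        stack = np.stack([base] * 4)
        aligned, _ = align_tomography_axis(stack, horizontal_offset_px=2.0)
        expected = fourier_shift(base, (0.0, 2.0))
        assert np.allclose(aligned[0], expected, atol=1e-9)

    def test_requires_two_projections(self, rng):
        with pytest.raises(ValueError):
            align_tomography_axis(rng.normal(size=(1, 16, 16)))
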