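"""Treatment of raw images: registration, background, averaging, alignment.

Shot-to-shot source pointing translates the image on the chip; all shots of
one projection are registered by normalized cross-correlation with sub-pixel
refinement (a paraboloid — two orthogonal parabolas — fit to the 3×3
neighbourhood of the correlation peak), shifted back in Fourier space,
averaged, and mean-pooled (binned).  The Gaussian beam profile is removed by
masking the sample with an edge-detection filter and fitting a second-order
polynomial to the remaining background.  The vertical tomography-axis
alignment cross-correlates row-integrated profiles; the horizontal
(rotation-axis) offset is a single manual constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import windows
from skimage.filters import threshold_otsu

from .beamline import TiltSeries


@dataclass(frozen=True)
class RegistrationResult:
    shift: tuple          # (dy, dx) pixels, sub-pixel
    peak_ncc: float       # normalized correlation at the (integer) peak


# ---------------------------------------------------------------------------
# shifting and correlation primitives
# ---------------------------------------------------------------------------

def fourier_shift(image: np.ndarray, shift) -> np.ndarray:
    """Sub-pixel translation by a phase ramp in Fourier space (periodic)."""
    image = np.asarray(image, float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    dy, dx = shift
    if dy == 0 and dx == 0:
        return image.copy()
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(image),
                                                      (dy, dx))))


def _parabolic_offset(m1, m0, p1) -> float:
    """Vertex offset of the parabola through (-1, m1), (0, m0), (1, p1)."""
    denom = m1 - 2.0 * m0 + p1
    if denom >= 0:  # not a maximum; stay on the grid point
        return 0.0
    return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))


def _apodize(image: np.ndarray, alpha: float = 0.25) -> np.ndarray:
    wy = windows.tukey(image.shape[0], alpha)
    wx = windows.tukey(image.shape[1], alpha)
    return image * wy[:, None] * wx[None, :]


def register(image: np.ndarray, reference: np.ndarray,
             search_radius: int = 10, apodize: bool = True,
             refine: int = 1) -> RegistrationResult:
    """Shift of ``image`` relative to ``reference`` by FFT-based NCC.

    Both images are mean-subtracted, Tukey-apodized (suppressing wrap-around
    ghosts) and cross-correlated; the integer peak within ``search_radius``
    is refined by two orthogonal parabolas through the 3×3 peak
    neighbourhood.  Ties break toward the smaller displacement.  ``refine``
    extra passes re-measure the residual after shifting the image back,
    where the parabolic estimate is essentially bias-free.  Applying
    :func:`fourier_shift` with the negated shift aligns ``image`` onto
    ``reference``.
    """
    result = _register_once(image, reference, search_radius, apodize)
    dy, dx = result.shift
    for _ in range(max(refine, 0)):
        if dy == 0.0 and dx == 0.0:
            break
        residual = _register_once(fourier_shift(image, (-dy, -dx)), reference,
                                  search_radius=2, apodize=apodize)
        dy += residual.shift[0]
        dx += residual.shift[1]
        result = RegistrationResult(shift=(dy, dx), peak_ncc=residual.peak_ncc)
    return result


def _register_once(image, reference, search_radius, apodize):
    image = np.asarray(image, float)
    reference = np.asarray(reference, float)
    if image.shape != reference.shape:
        raise ValueError("images must share a shape")
    a = image - image.mean()
    b = reference - reference.mean()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("normalized cross-correlation is undefined for a "
                         "constant image")
    if apodize:
        a, b = _apodize(a), _apodize(b)
    cc = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))))
    cc /= np.sqrt((a ** 2).sum() * (b ** 2).sum())
    cc = np.fft.fftshift(cc)
    cy, cx = image.shape[0] // 2, image.shape[1] // 2

    r = int(search_radius)
    win = cc[max(cy - r, 0):cy + r + 1, max(cx - r, 0):cx + r + 1]
    # tie-break toward the smaller displacement magnitude
    iy, ix = np.unravel_index(np.argmax(win), win.shape)
    peak = win[iy, ix]
    ties = np.argwhere(win >= peak - 1e-12)
    oy, ox = iy - min(cy, r), ix - min(cx, r)
    if len(ties) > 1:
        d2 = ((ties[:, 0] - min(cy, r)) ** 2 + (ties[:, 1] - min(cx, r)) ** 2)
        iy, ix = ties[int(np.argmin(d2))]
        oy, ox = iy - min(cy, r), ix - min(cx, r)
    py, px = cy + oy, cx + ox

    dy, dx = float(oy), float(ox)
    if 0 < py < cc.shape[0] - 1:
        dy += _parabolic_offset(cc[py - 1, px], cc[py, px], cc[py + 1, px])
    if 0 < px < cc.shape[1] - 1:
        dx += _parabolic_offset(cc[py, px - 1], cc[py, px], cc[py, px + 1])
    return RegistrationResult(shift=(dy, dx), peak_ncc=float(min(peak, 1.0)))


def ncc_shift_1d(profile: np.ndarray, reference: np.ndarray,
                 max_lag: int | None = None) -> float:
    """Sub-pixel lag of ``profile`` relative to ``reference`` (1D NCC).

    Circular correlation via the FFT, matching the periodic convention of
    :func:`fourier_shift`; parabolic refinement through the 3-point peak.
    """
    a = np.asarray(profile, float) - np.mean(profile)
    b = np.asarray(reference, float) - np.mean(reference)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant profiles")
    n = len(a)
    cc = np.fft.fftshift(np.real(np.fft.ifft(np.fft.fft(a) *
                                             np.conj(np.fft.fft(b)))))
    lags = np.arange(n) - n // 2
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        cc, lags = cc[keep], lags[keep]
    i = int(np.argmax(cc))
    lag = float(lags[i])
    if 0 < i < len(cc) - 1:
        lag += _parabolic_offset(cc[i - 1], cc[i], cc[i + 1])
    return lag


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def sample_mask(image: np.ndarray, smooth_sigma: float = 2.0,
                dilation_radius: int = 3) -> np.ndarray:
    """Boolean mask of the sample from a gradient-magnitude edge map.

    Gaussian-smoothed gradient magnitude, Otsu threshold, binary dilation —
    everything above threshold (plus a margin) is treated as sample.
    """
    grad = ndimage.gaussian_gradient_magnitude(np.asarray(image, float),
                                               smooth_sigma)
    if grad.max() <= 0:
        return np.zeros(image.shape, bool)
    mask = grad > threshold_otsu(grad)
    mask = ndimage.binary_dilation(mask, iterations=dilation_radius)
    # edge detection outlines the sample; fill so flat interiors are masked
    return ndimage.binary_fill_holes(mask)


def _poly2_fit(image: np.ndarray, keep: np.ndarray) -> np.ndarray:
    ny, nx = image.shape
    y = (np.arange(ny) - ny / 2.0) / ny
    x = (np.arange(nx) - nx / 2.0) / nx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    basis = np.stack([np.ones_like(yy), yy, xx, yy * xx, yy ** 2, xx ** 2])
    A = basis.reshape(6, -1).T[keep.ravel()]
    coef, *_ = np.linalg.lstsq(A, image.ravel()[keep.ravel()], rcond=None)
    return np.tensordot(coef, basis, axes=1)


def background_correct(image: np.ndarray, mask: np.ndarray | None = None,
                       mode: str = "subtract") -> np.ndarray:
    """Remove a smooth (second-order polynomial) background.

    The sample is masked out (``mask`` or :func:`sample_mask`); a 2D
    polynomial of total degree two (6 coefficients) is least-squares fitted
    to the background pixels.  ``mode="subtract"`` removes the fit and adds
    back its mean (preserving the intensity level); ``mode="divide"`` — the
    right operation for flat-field *ratio* images — divides by the fit so
    the background sits at exactly 1.
    """
    image = np.asarray(image, float)
    if mask is None:
        mask = sample_mask(image)
    keep = ~mask
    frac = keep.mean()
    if frac < 0.2:
        raise ValueError(f"background region too small ({frac:.0%} of pixels; "
                         "need >= 20%)")
    fit = _poly2_fit(image, keep)
    if mode == "subtract":
        return image - fit + fit.mean()
    if mode == "divide":
        floor = 1e-6 * max(abs(fit).max(), 1.0)
        return image / np.clip(fit, floor, None)
    raise ValueError("mode must be 'subtract' or 'divide'")


# ---------------------------------------------------------------------------
# per-projection pipeline
# ---------------------------------------------------------------------------

def average_and_bin(images: np.ndarray, shots_per: int,
                    bin_factor: int = 2) -> np.ndarray:
    """Per-angle mean of registered shots, then mean-pooling by ``bin_factor``.

    Mean (not sum) pooling keeps flat-field ratios normalized; total mean
    intensity is conserved exactly.
    """
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError("expected a (n_shots, ny, nx) stack")
    n, ny, nx = images.shape
    if n % shots_per:
        raise ValueError(f"stack length {n} not divisible by shots_per={shots_per}")
    if ny % bin_factor or nx % bin_factor:
        raise ValueError("image size must be divisible by the bin factor")
    proj = images.reshape(n // shots_per, shots_per, ny, nx).mean(axis=1)
    return proj.reshape(n // shots_per, ny // bin_factor, bin_factor,
                        nx // bin_factor, bin_factor).mean(axis=(2, 4))


def register_series(series: TiltSeries, search_radius: int = 10):
    """Flat-normalize and intra-angle register every shot of a tilt series.

    Each shot is divided by its flat reference, background-normalized in
    divide mode (absorbing the per-shot flux factor and residual envelope
    wander), then registered against the first shot of its projection.
    Returns (stack, shifts): the aligned ratio-image stack and the measured
    per-shot shifts in detector pixels.
    """
    per = series.shots_per_projection
    stack, shifts = [], []
    mask = None
    for i, shot in enumerate(series):
        ratio = np.asarray(shot.pixels, float)
        if shot.flat_reference is not None:
            ratio = ratio / np.clip(shot.flat_reference, 1e-12, None)
        if mask is None:
            mask = sample_mask(ratio)
        ratio = background_correct(ratio, mask=sample_mask(ratio), mode="divide")
        if i % per == 0:
            reference = ratio
            shift = (0.0, 0.0)
        else:
            res = register(ratio, reference, search_radius=search_radius)
            shift = res.shift
            ratio = fourier_shift(ratio, (-shift[0], -shift[1]))
        stack.append(ratio)
        shifts.append(shift)
    return np.stack(stack), np.asarray(shifts)


def align_tomography_axis(projections: np.ndarray,
                          horizontal_offset_px: float = 0.0,
                          max_lag: int | None = 10):
    """Vertical alignment of a projection stack + manual horizontal offset.

    Row-integrated profiles (sums perpendicular to the tomography axis) are
    cross-correlated against the stack-median profile with parabolic
    sub-pixel refinement; each projection is shifted back in Fourier space.
    The rotation-axis (horizontal) offset is a user-supplied constant applied
    uniformly, mirroring a manual alignment.

    Returns (aligned stack, vertical offsets in px).
    """
    projections = np.asarray(projections, float)
    if projections.ndim != 3 or projections.shape[0] < 2:
        raise ValueError("need a stack of at least two projections")
    profiles = projections.sum(axis=2)
    reference = np.median(profiles, axis=0)
    offsets = np.array([ncc_shift_1d(p, reference, max_lag=max_lag)
                        for p in profiles])
    aligned = np.stack([
        fourier_shift(img, (-dz, horizontal_offset_px))
        for img, dz in zip(projections, offsets)])
    return aligned, offsets
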