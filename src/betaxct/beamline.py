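"""Synthetic polychromatic beamline: radiographs and noisy tilt-series.

The forward model works in demagnified sample-plane coordinates: the
projected thickness T(r) of a single-material phantom is turned, energy bin
by energy bin, into the exit wave exp(ikδ(E)T − μ(E)T/2), propagated over
the defocusing distance D = d·l/(d+l) with the paraxial transfer function,
and the intensities are summed with the spectral weights times the detector
response (incoherent polychromatic sum).  Finite source size enters as a
Gaussian blur of σ·(M−1) referred to the detector plane.

A tilt-series acquisition adds the measured shot-to-shot statistics:
Gaussian source-pointing jitter (which translates the image), a truncated
Gaussian flux factor of 20% r.m.s., a Gaussian beam envelope on the chip
and Poisson shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .materials import MaterialOptics
from .phantom import Phantom, project
from .physics import BeamlineGeometry, energy_to_wavelength
from .propagate import fresnel_propagate
from .spectrum import Spectrum, identity_response


@dataclass
class Radiograph:
    """One detector exposure plus its ground-truth metadata."""

    pixels: np.ndarray              # detector counts (or normalized intensity)
    pixel_pitch_um: float           # at the detector
    angle_deg: float = 0.0
    shot_index: int = 0
    true_shift_um: tuple = (0.0, 0.0)   # (dy, dx) source-plane offset
    flat_reference: np.ndarray | None = None
    photon_total: float | None = None
    flux_factor: float = 1.0
    degenerate: bool = False

    def __post_init__(self):
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if np.any(np.asarray(self.pixels) < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class TiltSeries:
    """Ordered shots of a tomographic scan."""

    radiographs: list
    n_projections: int
    shots_per_projection: int
    geometry: BeamlineGeometry
    rng_seed: int | None = None

    def __post_init__(self):
        if len(self.radiographs) != self.n_projections * self.shots_per_projection:
            raise ValueError("series length must be n_projections × shots_per_projection")

    def __len__(self):
        return len(self.radiographs)

    def __iter__(self):
        return iter(self.radiographs)

    def __getitem__(self, i):
        return self.radiographs[i]

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([r.angle_deg for r in self.radiographs])

    def images(self) -> np.ndarray:
        return np.stack([r.pixels for r in self.radiographs])


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def radiograph_from_thickness(thickness_um: np.ndarray, spectrum: Spectrum,
                              geometry: BeamlineGeometry,
                              material: MaterialOptics,
                              source_sigma_um: float = 0.0,
                              detector_response=None,
                              detector_pixel_um: float = 22.5,
                              pad_factor: int = 2,
                              supersample="auto",
                              max_supersample: int = 8) -> np.ndarray:
    """Normalized polychromatic Fresnel intensity for a thickness map.

    ``thickness_um`` is sampled at the sample-plane pitch
    ``detector_pixel_um / M``; the returned intensity equals 1 in the
    unobstructed flat field.

    ``supersample`` refines the propagation grid before averaging back over
    detector pixels: the exit-wave phase gradient grows towards soft photon
    energies (δ/λ ∝ 1/E), and sampling it on the pixel grid aliases the
    strong-phase structure a real detector would simply integrate over.
    ``"auto"`` picks the refinement per energy bin so the largest per-sample
    phase step stays below π/2 (capped at ``max_supersample``); an integer
    applies one factor to every bin.
    """
    if source_sigma_um < 0:
        raise ValueError("source size must be >= 0")
    detector_response = detector_response or identity_response
    T0 = np.asarray(thickness_um, float)
    pixel_s0 = geometry.sample_plane_pixel(detector_pixel_um)

    energies = spectrum.energies
    w = spectrum.weights * detector_response(energies)
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum × response has zero weight")
    w = w / total
    # raises with the unsupported range if the optics table does not cover it
    mu = material.mu(energies)          # cm⁻¹
    delta = material.delta(energies)
    lam = energy_to_wavelength(energies)  # Å

    if supersample == "auto":
        gy, gx = np.gradient(T0, pixel_s0)
        grad_max = float(np.max(np.hypot(gy, gx)))  # μm per μm
        phase_step = (2 * np.pi * delta / (lam * 1e-4)) * grad_max * pixel_s0
        per_bin = np.clip(np.ceil(phase_step / (np.pi / 2)), 1,
                          max_supersample).astype(int)
    else:
        per_bin = np.full(len(energies), max(int(supersample), 1))

    intensity = np.zeros_like(T0)
    for ss in np.unique(per_bin[w > 1e-6]):
        group = (per_bin == ss) & (w > 1e-6)
        if ss > 1:
            T = ndimage.zoom(T0, ss, order=1, grid_mode=True, mode="nearest")
        else:
            T = T0
        pixel_s = pixel_s0 / ss
        partial = np.zeros_like(T)
        for wi, mu_i, d_i, lam_i in zip(w[group], mu[group], delta[group],
                                        lam[group]):
            phase = -2.0 * np.pi * d_i * T / (lam_i * 1e-4)   # λ in μm
            amplitude = np.exp(-0.5 * mu_i * T * 1e-4)        # T in cm
            field = (amplitude * np.exp(1j * phase)).astype(np.complex64)
            if geometry.D > 0:
                # padding only matters while the Fresnel kernel spread
                # sqrt(λD) is an appreciable fraction of the field width
                kernel_um = np.sqrt(lam_i * 1e-10 * geometry.D) * 1e6
                pad = pad_factor if kernel_um > 0.01 * min(T.shape) * pixel_s \
                    else 1
                # and must grow until the transfer function stays sampled
                need = lam_i * 1e-10 * geometry.D / (pixel_s * 1e-6) ** 2
                need_pad = int(np.ceil(need / min(T.shape)))
                if need_pad > 1:
                    pad = max(pad, need_pad + 1)
                field = fresnel_propagate(field, lam_i, geometry.D, pixel_s,
                                          pad_factor=pad)
            partial += wi * np.abs(field) ** 2
        if ss > 1:
            ny, nx = partial.shape
            partial = partial.reshape(ny // ss, ss, nx // ss, ss).mean(
                axis=(1, 3))
        intensity += partial

    # bins skipped as negligible still carry their (tiny) flat-field weight
    skipped = w[(w <= 1e-6)].sum()
    intensity += skipped

    if source_sigma_um > 0:
        # projected source blur: σ·(M−1) at the detector = σ·(M−1)/M here
        sigma_px = source_sigma_um * (geometry.M - 1.0) / geometry.M / pixel_s0
        if sigma_px > 1e-3:
            intensity = ndimage.gaussian_filter(intensity, sigma_px,
                                                mode="nearest")
    return intensity


def polychromatic_radiograph(phantom: Phantom, spectrum: Spectrum,
                             geometry: BeamlineGeometry,
                             source_sigma_um: float = 0.0,
                             detector_response=None,
                             detector_pixel_um: float = 22.5,
                             angle_deg: float = 0.0) -> Radiograph:
    """Simulate one noiseless, flat-normalized radiograph of a phantom.

    The phantom voxel size must equal the sample-plane pixel pitch
    (detector pitch / M) so that projection and detector grids coincide.
    """
    pixel_s = geometry.sample_plane_pixel(detector_pixel_um)
    if abs(phantom.voxel_size_um - pixel_s) > 1e-6 * pixel_s:
        raise ValueError(
            f"phantom voxel size {phantom.voxel_size_um:.4f} μm must match the "
            f"sample-plane pixel {pixel_s:.4f} μm")
    T = project(phantom, angle_deg)
    intensity = radiograph_from_thickness(
        T, spectrum, geometry, phantom.material, source_sigma_um,
        detector_response, detector_pixel_um)
    return Radiograph(pixels=intensity, pixel_pitch_um=detector_pixel_um,
                      angle_deg=angle_deg)


def gaussian_envelope(shape, fwhm_fraction: float = 2.0) -> np.ndarray:
    """Gaussian beam footprint on the chip, peak-normalized.

    ``fwhm_fraction`` is the envelope FWHM in units of the field-of-view
    width (a free generator parameter; the measured footprint was Gaussian
    but its width is not constrained).
    """
    ny, nx = shape
    fwhm = fwhm_fraction * max(ny, nx)
    sigma = fwhm / 2.3548200450309493
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    return np.exp(-(y[:, None] ** 2 + x[None, :] ** 2) / (2 * sigma ** 2))


def _fourier_shift_image(image: np.ndarray, shift_px) -> np.ndarray:
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(image),
                                                      shift_px)))


def acquire_tilt_series(phantom: Phantom, spectrum: Spectrum,
                        geometry: BeamlineGeometry,
                        n_projections: int = 360,
                        shots_per_projection: int = 4,
                        jitter_v_um: float = 12.0,
                        jitter_h_um: float = 18.0,
                        flux_rms: float = 0.20,
                        photons_per_shot: float = 1.6e7,
                        source_sigma_um: float = 1.8,
                        detector_response=None,
                        detector_pixel_um: float = 22.5,
                        envelope_fwhm_fraction: float = 2.0,
                        seed: int | None = None) -> TiltSeries:
    """Full noisy scan: ``n_projections`` angles over 360°, several shots each.

    Per shot: a Gaussian source-position offset (12/18 μm r.m.s. vertical/
    horizontal by default) translates the image by (M−1)/M × offset in
    sample-plane coordinates; a truncated-Gaussian flux factor of r.m.s.
    ``flux_rms`` scales the expected counts; the Gaussian beam envelope
    (integrating to ``photons_per_shot``) sets the per-pixel expectation;
    Poisson noise is drawn on top.  ``flat_reference`` stores the nominal
    (unit-flux, centred) envelope — the information a flat-field measurement
    would give — so normalization and background correction stay honest.

    Identical seeds give bit-identical series.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for a stochastic acquisition")
    rng = np.random.default_rng(seed)
    detector_response = detector_response or identity_response
    pixel_s = geometry.sample_plane_pixel(detector_pixel_um)
    angles = np.arange(n_projections) * 360.0 / n_projections

    envelope = gaussian_envelope(phantom.shape[:2],
                                 envelope_fwhm_fraction)
    envelope = envelope * (photons_per_shot / envelope.sum())
    # flux factor: Gaussian of σ/μ = flux_rms truncated at zero
    flux_dist = truncnorm((0.0 - 1.0) / flux_rms, np.inf, loc=1.0,
                          scale=flux_rms)

    shots = []
    shot_index = 0
    for angle in angles:
        base = radiograph_from_thickness(
            project(phantom, angle), spectrum, geometry, phantom.material,
            source_sigma_um, detector_response, detector_pixel_um)
        for _ in range(shots_per_projection):
            dy, dx = rng.normal(0.0, [jitter_v_um, jitter_h_um])
            flux = float(flux_dist.rvs(random_state=rng))
            # source offset Δ moves the object image by Δ(M−1) on the detector
            shift_px = (np.array([dy, dx]) * (geometry.M - 1.0)
                        / detector_pixel_um)
            shifted = _fourier_shift_image(base, shift_px)
            expected = np.clip(flux * envelope * shifted, 0.0, None)
            counts = rng.poisson(expected).astype(np.float32)
            total = float(counts.sum())
            shots.append(Radiograph(
                pixels=counts, pixel_pitch_um=detector_pixel_um,
                angle_deg=float(angle), shot_index=shot_index,
                true_shift_um=(float(dy), float(dx)),
                flat_reference=envelope, photon_total=total,
                flux_factor=flux, degenerate=(total == 0.0)))
            shot_index += 1
    return TiltSeries(shots, n_projections, shots_per_projection, geometry,
                      rng_seed=seed)


# ---------------------------------------------------------------------------
# wire image for source-size analysis (independent FFT route)
# ---------------------------------------------------------------------------

def simulate_wire_image(sigma_um: float, spectrum: Spectrum,
                        geometry: BeamlineGeometry,
                        wire_diameter_um: float = 100.0,
                        detector_response=None,
                        detector_pixel_um: float = 22.5,
                        n_cols: int = 160, n_rows: int = 64,
                        curvature_px: float = 0.0,
                        tilt_deg: float = 0.0,
                        supersample: int = 8,
                        photons_per_pixel: float | None = None,
                        seed: int | None = None) -> Radiograph:
    """Radiograph of a vertical opaque wire via FFT Fresnel propagation.

    Deliberately independent of the closed-form Fresnel-integral model used
    for fitting: each row is a 1D field with a hard opaque strip (sub-pixel
    edge coverage), propagated by the angular-spectrum kernel per energy
    bin, blurred by the projected source and integrated over detector
    pixels.  ``curvature_px``/``tilt_deg`` bend or tilt the wire axis to
    exercise the row-alignment step; optional Poisson noise at
    ``photons_per_pixel`` expected flat-field counts.
    """
    detector_response = detector_response or identity_response
    pixel_s = geometry.sample_plane_pixel(detector_pixel_um)
    dx = pixel_s / supersample
    n_fine = n_cols * supersample
    radius = wire_diameter_um / 2.0

    w = spectrum.weights * detector_response(spectrum.energies)
    w = w / w.sum()
    lam = energy_to_wavelength(spectrum.energies)

    x = (np.arange(n_fine) - (n_fine - 1) / 2.0) * dx
    rows = np.arange(n_rows) - (n_rows - 1) / 2.0
    # wire-centre offset per row (μm at the sample plane)
    centre = (curvature_px * (rows / max(n_rows / 2.0, 1)) ** 2 * pixel_s
              + np.tan(np.radians(tilt_deg)) * rows * pixel_s)

    sigma_det = sigma_um * (geometry.M - 1.0)      # blur at detector, μm
    sigma_fine = sigma_det / geometry.M / dx       # in supersample units

    image = np.empty((n_rows, n_cols))
    profile_cache: dict[float, np.ndarray] = {}
    for r, c in enumerate(centre):
        key = round(float(c), 6)
        if key not in profile_cache:
            inten = np.zeros(n_fine)
            # sub-pixel edge coverage of the opaque strip |x−c| < radius
            cover = np.clip((radius - np.abs(x - c)) / dx + 0.5, 0.0, 1.0)
            amp = np.sqrt(1.0 - cover)
            for wi, lam_i in zip(w, lam):
                if wi == 0.0:
                    continue
                # pad enough that the transfer function stays Nyquist-sampled
                need = lam_i * 1e-10 * geometry.D / (dx * 1e-6) ** 2
                pad = max(4, int(np.ceil(need / n_fine)) + 1)
                field = fresnel_propagate(amp[None, :].astype(complex), lam_i,
                                          geometry.D, dx, pad_factor=pad)
                inten += wi * np.abs(field[0]) ** 2
            if sigma_fine > 1e-3:
                inten = ndimage.gaussian_filter1d(inten, sigma_fine,
                                                  mode="nearest")
            profile_cache[key] = inten.reshape(n_cols, supersample).mean(axis=1)
        image[r] = profile_cache[key]

    if photons_per_pixel is not None:
        if seed is None:
            raise ValueError("a seed is mandatory when adding shot noise")
        rng = np.random.default_rng(seed)
        image = rng.poisson(np.clip(image, 0, None)
                            * photons_per_pixel) / photons_per_pixel
    return Radiograph(pixels=image, pixel_pitch_um=detector_pixel_um)
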