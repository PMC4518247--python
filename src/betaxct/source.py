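"""Source diagnostics: filter-stack spectroscopy and wire source-size fit.

Two measurements pin down the source.  (1) The X-ray spectrum is recovered
from the transmission of a stepped filter stack by fitting the one-parameter
synchrotron shape S(E/E_c): with ~10 thickness steps the critical energy is
the only spectral degree of freedom that is well constrained, matching the
synchrotron-like continuum the emission process produces.  (2) The r.m.s.
source size follows from the Fresnel diffraction pattern of an opaque wire:
the pattern is modelled per energy bin with the closed-form Fresnel
integrals, blurred by the projected source (σ·(M−1) at the detector), and
the measured first overshoot — which carries essentially all of the source
size information — is matched in least squares over a σ grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .materials import MaterialOptics, aluminium
from .physics import BeamlineGeometry, energy_to_wavelength
from .preprocess import fourier_shift, ncc_shift_1d
from .propagate import opaque_strip_intensity
from .spectrum import Spectrum, filter_transmission, identity_response, \
    synchrotron_spectrum


# ---------------------------------------------------------------------------
# filter-stack spectroscopy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterStackMeasurement:
    """Detector signal behind each overall filter thickness, plus reference."""

    thicknesses_um: np.ndarray
    transmitted_signal: np.ndarray
    reference_signal: float
    material: MaterialOptics

    def __post_init__(self):
        t = np.asarray(self.thicknesses_um, float)
        s = np.asarray(self.transmitted_signal, float)
        if np.any(t <= 0):
            raise ValueError("filter thicknesses must be positive")
        if np.any(s < 0) or self.reference_signal <= 0:
            raise ValueError("signals must be non-negative, reference positive")
        object.__setattr__(self, "thicknesses_um", t)
        object.__setattr__(self, "transmitted_signal", s)

    @property
    def ratios(self) -> np.ndarray:
        return self.transmitted_signal / self.reference_signal

    def to_csv(self, path) -> None:
        pd.DataFrame({"thickness_um": self.thicknesses_um,
                      "signal": self.transmitted_signal,
                      "reference": self.reference_signal}).to_csv(path,
                                                                  index=False)

    @classmethod
    def from_csv(cls, path, material: MaterialOptics | None = None):
        df = pd.read_csv(path)
        return cls(df["thickness_um"].to_numpy(), df["signal"].to_numpy(),
                   float(df["reference"].iloc[0]), material or aluminium())


@dataclass(frozen=True)
class SpectrumFit:
    spectrum: Spectrum            # fitted spectrum behind the blocking foil
    E_c_keV: float
    amplitude: float
    misfit: float
    predicted_ratios: np.ndarray
    measured_ratios: np.ndarray


def _predicted_ratios(E_c, energies, mu_t, base_weights):
    """Detector-weighted transmission of each filter step for one E_c."""
    s = synchrotron_spectrum(E_c, energies).weights * base_weights
    denom = s.sum()
    return (s[None, :] * np.exp(-mu_t)).sum(axis=1) / denom


def reconstruct_spectrum(meas: FilterStackMeasurement,
                         detector_response=None,
                         energy_grid=None,
                         base_filter_um: float = 10.0,
                         base_filter_material: MaterialOptics | None = None,
                         E_c_bounds=(1.0, 20.0)) -> SpectrumFit:
    """Least-squares fit of (E_c, amplitude) to filter-stack transmissions.

    The model transmission of step ``t`` is
    Σ S(E;E_c)·resp(E)·B(E)·exp(−μ(E)t) / Σ S·resp·B, with B the
    transmission of the always-present blocking foil (``base_filter_um`` of
    ``base_filter_material``, aluminium by default).  The amplitude is
    solved analytically for each trial E_c; E_c is found by bounded 1D
    minimization.  Returns the fitted spectrum *behind* the blocking foil.
    """
    if len(np.unique(meas.thicknesses_um)) < 3:
        raise ValueError("underdetermined: need >= 3 distinct filter "
                         "thicknesses to constrain (E_c, amplitude)")
    detector_response = detector_response or identity_response
    base_mat = base_filter_material or aluminium()
    energies = np.asarray(energy_grid if energy_grid is not None
                          else np.linspace(1.0, 20.0, 96), float)

    base = detector_response(energies) * np.exp(
        -base_mat.mu(energies) * base_filter_um * 1e-4)
    mu_t = np.outer(meas.thicknesses_um * 1e-4, meas.material.mu(energies))
    measured = meas.ratios

    def misfit_of(log_ec):
        pred = _predicted_ratios(np.exp(log_ec), energies, mu_t, base)
        amp = float(pred @ measured / (pred @ pred))
        return float(((amp * pred - measured) ** 2).sum()), amp, pred

    res = minimize_scalar(lambda x: misfit_of(x)[0],
                          bounds=(np.log(E_c_bounds[0]), np.log(E_c_bounds[1])),
                          method="bounded",
                          options={"xatol": 1e-6})
    if not res.success:
        raise RuntimeError(f"spectrum fit did not converge: {res.message}")
    E_c = float(np.exp(res.x))
    misfit, amp, pred = misfit_of(res.x)
    fitted = filter_transmission(base_mat, base_filter_um,
                                 synchrotron_spectrum(E_c, energies))
    return SpectrumFit(spectrum=fitted.normalized(), E_c_keV=E_c,
                       amplitude=amp, misfit=misfit, predicted_ratios=pred,
                       measured_ratios=measured)


def simulate_filter_measurement(E_c: float, thicknesses_um,
                                material: MaterialOptics | None = None,
                                detector_response=None,
                                energy_grid=None,
                                base_filter_um: float = 10.0,
                                reference_signal: float = 1e6,
                                noise_rms: float = 0.0,
                                seed: int | None = None) -> FilterStackMeasurement:
    """Synthesize a filter-cake measurement from a known critical energy."""
    material = material or aluminium()
    detector_response = detector_response or identity_response
    energies = np.asarray(energy_grid if energy_grid is not None
                          else np.linspace(1.0, 20.0, 96), float)
    base = detector_response(energies) * np.exp(
        -material.mu(energies) * base_filter_um * 1e-4)
    thicknesses = np.asarray(thicknesses_um, float)
    mu_t = np.outer(thicknesses * 1e-4, material.mu(energies))
    ratios = _predicted_ratios(E_c, energies, mu_t, base)
    if noise_rms > 0:
        if seed is None:
            raise ValueError("a seed is mandatory for noisy measurements")
        rng = np.random.default_rng(seed)
        ratios = ratios * (1.0 + rng.normal(0.0, noise_rms, ratios.shape))
        ratios = np.clip(ratios, 0.0, None)
    return FilterStackMeasurement(thicknesses, ratios * reference_signal,
                                  reference_signal, material)


# ---------------------------------------------------------------------------
# wire diffraction model and source-size estimation
# ---------------------------------------------------------------------------

def model_wire_profile(sigma_um: float, spectrum: Spectrum,
                       geometry: BeamlineGeometry,
                       wire_diameter_um: float = 100.0,
                       detector_response=None,
                       detector_pixel_um: float = 22.5,
                       n_pixels: int = 160,
                       supersample: int = 8,
                       centre_um: float = 0.0) -> np.ndarray:
    """Pixel-integrated polychromatic Fresnel pattern of an opaque wire.

    Per energy bin the closed-form two-edge (opaque strip) pattern is
    evaluated at the demagnified coordinate x/M over the defocusing distance
    D; the spectrally weighted sum is blurred by the projected source
    (Gaussian of σ·(M−1) at the detector) and averaged over detector pixels.
    Far-field intensity is normalized to 1.
    """
    if sigma_um < 0:
        raise ValueError("source size must be >= 0")
    detector_response = detector_response or identity_response
    w = spectrum.weights * detector_response(spectrum.energies)
    w = w / w.sum()
    lam = energy_to_wavelength(spectrum.energies)

    fine = detector_pixel_um / supersample
    n_fine = n_pixels * supersample
    x_det = (np.arange(n_fine) - (n_fine - 1) / 2.0) * fine - centre_um
    x_sample = x_det / geometry.M

    profile = np.zeros(n_fine)
    for wi, lam_i in zip(w, lam):
        if wi == 0.0:
            continue
        profile += wi * opaque_strip_intensity(
            x_sample, wire_diameter_um / 2.0, lam_i, geometry.D)
    sigma_det = sigma_um * (geometry.M - 1.0) / fine
    if sigma_det > 1e-3:
        profile = ndimage.gaussian_filter1d(profile, sigma_det, mode="nearest")
    return profile.reshape(n_pixels, supersample).mean(axis=1)


@dataclass(frozen=True)
class SourceSizeFit:
    sigma_best_um: float
    sigma_grid_um: np.ndarray
    misfit: np.ndarray
    confidence_um: float           # half-width from the misfit curvature
    offset_px: float               # fitted lateral wire position
    profile: np.ndarray            # aligned, normalized measured profile
    model_best: np.ndarray         # best-fit model on the same pixel grid


def _overshoot_window(model: np.ndarray, edges_px) -> np.ndarray:
    """Pixels from each geometric edge out to the first local minimum past
    the first diffraction maximum (where the source-size information lives)."""
    keep = np.zeros(len(model), bool)
    for edge, direction in edges_px:
        i = int(round(edge))
        i = max(1, min(len(model) - 2, i))
        j = i
        # walk outward to the first local maximum, then on to the next minimum
        while 1 <= j + direction <= len(model) - 2 and \
                model[j + direction] >= model[j]:
            j += direction
        k = j
        while 1 <= k + direction <= len(model) - 2 and \
                model[k + direction] <= model[k]:
            k += direction
        lo, hi = sorted((i, k))
        keep[lo:hi + 1] = True
    return keep


def align_wire_rows(image: np.ndarray, max_lag: int = 8) -> np.ndarray:
    """Curvature-corrected vertical sum of wire-profile rows.

    Each row is cross-correlated against the column-median profile (3-point
    parabolic sub-pixel peak), shifted back in Fourier space, and the rows
    are averaged into one high-SNR profile.
    """
    image = np.asarray(image, float)
    reference = np.median(image, axis=0)
    aligned = np.empty_like(image)
    for i, row in enumerate(image):
        lag = ncc_shift_1d(row, reference, max_lag=max_lag)
        aligned[i] = fourier_shift(row[None, :], (0.0, -lag))[0]
    return aligned.mean(axis=0)


def estimate_source_size(image, spectrum: Spectrum, geometry: BeamlineGeometry,
                         sigma_grid_um=None,
                         wire_diameter_um: float = 100.0,
                         detector_response=None,
                         detector_pixel_um: float = 22.5,
                         min_contrast: float = 0.1) -> SourceSizeFit:
    """Fit the r.m.s. source size to a measured wire radiograph.

    Steps: row alignment and vertical summation (wire curvature corrected by
    cross-correlation between rows); normalization to the far-field level;
    lateral wire-position fit; then a least-squares scan of
    :func:`model_wire_profile` over ``sigma_grid_um`` restricted to the
    first-overshoot window, with parabolic refinement of the minimum.
    """
    pixels = getattr(image, "pixels", image)
    detector_pixel_um = getattr(image, "pixel_pitch_um", detector_pixel_um)
    if sigma_grid_um is None:
        sigma_grid_um = np.arange(0.5, 4.01, 0.1)
    sigma_grid_um = np.asarray(sigma_grid_um, float)

    profile = align_wire_rows(np.asarray(pixels, float))
    n = len(profile)
    outer = max(4, n // 10)
    far = 0.5 * (profile[:outer].mean() + profile[-outer:].mean())
    if far <= 0:
        raise ValueError("no far-field signal in the wire image")
    profile = profile / far
    if (profile.max() - profile.min()) / profile.max() < min_contrast:
        raise ValueError("no detectable wire edge: contrast below threshold")

    kwargs = dict(spectrum=spectrum, geometry=geometry,
                  wire_diameter_um=wire_diameter_um,
                  detector_response=detector_response,
                  detector_pixel_um=detector_pixel_um, n_pixels=n)

    # lateral position: coarse centroid of the absorption dip, then a fine
    # scan minimizing the full-profile misfit at a mid-grid sigma
    absorb = np.clip(1.0 - profile, 0.0, None)
    x_px = np.arange(n, dtype=float)
    coarse = float((absorb * x_px).sum() / absorb.sum() - (n - 1) / 2.0)
    sigma_mid = float(sigma_grid_um[len(sigma_grid_um) // 2])

    def model_at(offset_px, sigma):
        return model_wire_profile(sigma, centre_um=-offset_px * detector_pixel_um,
                                  **kwargs)

    offsets = coarse + np.linspace(-1.0, 1.0, 21)
    errs = [((model_at(o, sigma_mid) - profile) ** 2).sum() for o in offsets]
    i = int(np.argmin(errs))
    offset = float(offsets[i])
    if 0 < i < len(offsets) - 1:
        denom = errs[i - 1] - 2 * errs[i] + errs[i + 1]
        if denom > 0:
            offset += 0.5 * (errs[i - 1] - errs[i + 1]) / denom * 0.1

    # misfit window from the sharp-source model
    sharp = model_at(offset, 0.0)
    centre_px = (n - 1) / 2.0 + offset
    half_det = wire_diameter_um / 2.0 * geometry.M / detector_pixel_um
    edges = [(centre_px - half_det, -1), (centre_px + half_det, +1)]
    window = _overshoot_window(sharp, edges)

    misfit = np.empty(len(sigma_grid_um))
    models = []
    for k, s in enumerate(sigma_grid_um):
        m = model_at(offset, s)
        amp = float(m[window] @ profile[window] / (m[window] @ m[window]))
        misfit[k] = ((amp * m[window] - profile[window]) ** 2).sum()
        models.append(amp * m)

    j = int(np.argmin(misfit))
    sigma_best = float(sigma_grid_um[j])
    step = float(np.mean(np.diff(sigma_grid_um)))
    confidence = step
    if 0 < j < len(misfit) - 1:
        denom = misfit[j - 1] - 2 * misfit[j] + misfit[j + 1]
        if denom > 0:
            sigma_best += 0.5 * (misfit[j - 1] - misfit[j + 1]) / denom * step
            # half-width where the parabola rises by the per-window residual
            dof = max(int(window.sum()) - 2, 1)
            confidence = max(step / 2.0,
                             float(np.sqrt(2.0 * misfit[j] / dof / denom)) * step)
    return SourceSizeFit(sigma_best_um=sigma_best, sigma_grid_um=sigma_grid_um,
                         misfit=misfit, confidence_um=confidence,
                         offset_px=offset, profile=profile,
                         model_best=models[j])
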