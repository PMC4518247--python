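"""Free-space Fresnel propagation: FFT transfer function and closed forms.

The FFT route (:func:`fresnel_propagate`) is the workhorse of the synthetic
beamline; the closed-form knife-edge/strip patterns built from the Fresnel
integrals C(w), S(w) serve as the independent oracle and as the model for
the wire-based source-size fit.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft
from scipy.special import fresnel


def fresnel_propagate(field: np.ndarray, wavelength_A: float, distance_m: float,
                      pixel_um: float, pad_factor: int = 1) -> np.ndarray:
    """Propagate a complex scalar field by the paraxial transfer function.

    Parameters
    ----------
    field : complex 2D array
        Wave at the input plane, sampled on a square grid of pitch
        ``pixel_um``.
    wavelength_A, distance_m, pixel_um : float
        Wavelength (Å), propagation distance (m), grid pitch (μm).
    pad_factor : int
        Edge-replicating padding factor (>=1) applied before the FFT to
        suppress periodic wrap-around; the output is cropped back.

    The transfer function H = exp(-iπλz(fx²+fy²)) is unimodular, so total
    intensity is conserved exactly (before any cropping).

    Raises
    ------
    ValueError
        If the grid undersamples the transfer function, i.e. if
        λ·z > N·Δx² where N is the (padded) grid length: the quadratic
        phase of H then aliases and the result is unphysical.
    """
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("field must be 2D")
    if distance_m == 0:
        return field.copy()
    lam = wavelength_A * 1e-10
    dx = pixel_um * 1e-6
    if pad_factor > 1:
        # singleton axes stay singleton (1D propagation)
        py = field.shape[0] * (pad_factor - 1) // 2 if field.shape[0] > 1 else 0
        px = field.shape[1] * (pad_factor - 1) // 2 if field.shape[1] > 1 else 0
        work = np.pad(field, ((py, py), (px, px)), mode="edge")
    else:
        py = px = 0
        work = field
    # singleton axes carry no transverse frequency content (1D propagation)
    n_min = min(n for n in work.shape if n > 1)
    if lam * abs(distance_m) > n_min * dx**2:
        raise ValueError(
            "undersampled propagation: require λ·D <= N·Δx², got "
            f"λD = {lam * abs(distance_m):.3e} m² > N·Δx² = {n_min * dx**2:.3e} m² "
            f"(N = {n_min}, Δx = {pixel_um} μm); refine sampling or pad more")
    fy = np.fft.fftfreq(work.shape[0], d=dx)
    fx = np.fft.fftfreq(work.shape[1], d=dx)
    H = np.exp(-1j * np.pi * lam * distance_m *
               (fy[:, None] ** 2 + fx[None, :] ** 2))
    if work.dtype == np.complex64:
        H = H.astype(np.complex64)  # single precision in, single out
    out = sp_fft.ifft2(sp_fft.fft2(work) * H)
    if pad_factor > 1:
        out = out[py:py + field.shape[0], px:px + field.shape[1]]
    return out


# ---------------------------------------------------------------------------
# closed-form Fresnel diffraction (oracle + wire model)
# ---------------------------------------------------------------------------

def _fresnel_cs(w):
    s, c = fresnel(w)
    return c, s


def knife_edge_amplitude(x_um, wavelength_A: float, distance_m: float) -> np.ndarray:
    """Complex amplitude behind an opaque half-plane covering x < 0.

    Evaluated at transverse positions ``x_um`` a distance ``distance_m``
    downstream, unit incident plane wave.  |U|² = 1/4 at the geometric edge
    and overshoots to ≈1.37 at the first fringe.
    """
    lam = wavelength_A * 1e-10
    w = np.asarray(x_um, float) * 1e-6 * np.sqrt(2.0 / (lam * distance_m))
    c, s = _fresnel_cs(w)
    return ((c + 0.5) + 1j * (s + 0.5)) / (1 + 1j)


def knife_edge_intensity(x_um, wavelength_A: float, distance_m: float) -> np.ndarray:
    """|U|² of :func:`knife_edge_amplitude` — the classic edge pattern."""
    return np.abs(knife_edge_amplitude(x_um, wavelength_A, distance_m)) ** 2


def opaque_strip_intensity(x_um, half_width_um: float, wavelength_A: float,
                           distance_m: float) -> np.ndarray:
    """Fresnel pattern of an opaque strip |x| < a (two opposed knife edges).

    U(x) = 1 - (1/(1+i)) ∫ over the blocked interval of the Fresnel kernel;
    as a → ∞ with one edge in the window this reduces to the knife edge.
    """
    lam = wavelength_A * 1e-10
    scale = np.sqrt(2.0 / (lam * distance_m))
    x = np.asarray(x_um, float) * 1e-6
    t1 = (-half_width_um * 1e-6 - x) * scale
    t2 = (half_width_um * 1e-6 - x) * scale
    c1, s1 = _fresnel_cs(t1)
    c2, s2 = _fresnel_cs(t2)
    u = 1.0 - ((c2 - c1) + 1j * (s2 - s1)) / (1 + 1j)
    return np.abs(u) ** 2
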