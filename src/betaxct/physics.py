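"""Closed-form physical relations of a point-projection betatron beamline.

Every public function takes and returns the units printed on the beamline
log book — photon energies in keV, wavelengths in Å, transverse lengths in
μm, beamline distances in m, densities in cm⁻³ — and converts to SI
internally.  Constants are pinned to CODATA 2018 (via :mod:`scipy.constants`)
so that the worked examples are reproducible to the last printed digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 constants, in the unit system used by the public API."""

    c: float = _const.c                      # speed of light, m/s
    e: float = _const.e                      # elementary charge, C
    m_e: float = _const.m_e                  # electron rest mass, kg
    eps0: float = _const.epsilon_0           # vacuum permittivity, F/m
    r_e: float = _const.physical_constants["classical electron radius"][0]  # m
    hbar_keV_s: float = _const.hbar / _const.e / 1e3          # ħ, keV·s
    hc_keV_A: float = _const.h * _const.c / _const.e * 1e7    # h·c, keV·Å
    mec2_keV: float = _const.physical_constants[
        "electron mass energy equivalent in MeV"][0] * 1e3    # keV


CONSTANTS = PhysicalConstants()


# ---------------------------------------------------------------------------
# beamline geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamlineGeometry:
    """Point-projection imaging arm.

    Parameters
    ----------
    l : float
        Source–sample distance in metres (> 0).
    d : float
        Sample–detector distance in metres (>= 0).

    Derived attributes: magnification ``M = (l+d)/l``, defocusing distance
    ``D = d*l/(d+l)`` (the effective free-propagation distance governing the
    Fresnel regime), and total source–detector distance ``R_total = l+d``.
    """

    l: float
    d: float
    M: float = field(init=False)
    D: float = field(init=False)
    R_total: float = field(init=False)

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"source-sample distance must be > 0, got l={self.l}")
        if self.d < 0:
            raise ValueError(f"sample-detector distance must be >= 0, got d={self.d}")
        object.__setattr__(self, "M", (self.l + self.d) / self.l)
        object.__setattr__(self, "D",
                           0.0 if self.d == 0 else self.d * self.l / (self.d + self.l))
        object.__setattr__(self, "R_total", self.l + self.d)

    def sample_plane_pixel(self, detector_pixel_um: float) -> float:
        """Detector pixel pitch demagnified to the sample plane (μm)."""
        return detector_pixel_um / self.M


def make_geometry(l: float, d: float) -> BeamlineGeometry:
    """Build a :class:`BeamlineGeometry` from distances in metres."""
    return BeamlineGeometry(l=l, d=d)


# ---------------------------------------------------------------------------
# photons
# ---------------------------------------------------------------------------

def energy_to_wavelength(energy_keV):
    """Photon energy (keV) → wavelength (Å);  λ = hc/E."""
    energy_keV = np.asarray(energy_keV, dtype=float)
    if np.any(energy_keV <= 0):
        raise ValueError("photon energy must be positive")
    out = CONSTANTS.hc_keV_A / energy_keV
    return out if out.ndim else float(out)


def wavelength_to_energy(wavelength_A):
    """Wavelength (Å) → photon energy (keV); inverse of energy_to_wavelength."""
    wavelength_A = np.asarray(wavelength_A, dtype=float)
    if np.any(wavelength_A <= 0):
        raise ValueError("wavelength must be positive")
    out = CONSTANTS.hc_keV_A / wavelength_A
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# plasma and betatron motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmaState:
    """Operating point of the wakefield: density, electron energy, amplitude.

    n_e is the plasma electron density in cm⁻³, gamma the electron Lorentz
    factor, r_beta the betatron oscillation amplitude in μm.
    """

    n_e: float
    gamma: float = 1.0
    r_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.n_e <= 0:
            raise ValueError("plasma density must be positive")
        if self.gamma < 1:
            raise ValueError("Lorentz factor must be >= 1")
        if self.r_beta < 0:
            raise ValueError("betatron amplitude must be >= 0")


def gamma_from_energy(energy_MeV: float) -> float:
    """Lorentz factor of an electron of given kinetic-dominated energy (MeV)."""
    return energy_MeV * 1e3 / CONSTANTS.mec2_keV


def plasma_frequency(n_e: float) -> float:
    """Plasma frequency ω_p = sqrt(n_e e²/(ε0 m_e)) in rad/s for n_e in cm⁻³."""
    if n_e <= 0:
        raise ValueError("plasma density must be positive")
    n_si = n_e * 1e6  # cm⁻³ → m⁻³
    return float(np.sqrt(n_si * CONSTANTS.e**2 / (CONSTANTS.eps0 * CONSTANTS.m_e)))


def plasma_wavelength(n_e: float) -> float:
    """Plasma wavelength λ_p = 2πc/ω_p in μm; sets the wakefield radial scale."""
    return 2 * np.pi * CONSTANTS.c / plasma_frequency(n_e) * 1e6


def betatron_frequency(state: PlasmaState) -> float:
    """Betatron frequency ω_β = ω_p/sqrt(2γ) in rad/s."""
    return plasma_frequency(state.n_e) / np.sqrt(2 * state.gamma)


def opening_angle(state: PlasmaState) -> float:
    """Radiation opening angle θ = r_β ω_β / c (rad)."""
    return state.r_beta * 1e-6 * betatron_frequency(state) / CONSTANTS.c


def wiggler_parameter(state: PlasmaState) -> float:
    """Wiggler parameter K ≈ γθ.  K >> 1 puts the emission in the wiggler
    regime where the harmonics merge into a synchrotron-like continuum."""
    return state.gamma * opening_angle(state)


def critical_energy(state: PlasmaState) -> float:
    """Critical energy E_c = (3/2) ħ K γ² ω_β of the continuum, in keV."""
    K = wiggler_parameter(state)
    return 1.5 * CONSTANTS.hbar_keV_s * K * state.gamma**2 * betatron_frequency(state)


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def coherence_length(wavelength_A: float, R_m: float, sigma_um: float) -> float:
    """Transverse coherence length l_t = λ·R/σ in μm.

    λ in Å, R the propagation distance from the source in m, σ the r.m.s.
    source size in μm.
    """
    if wavelength_A <= 0 or R_m <= 0:
        raise ValueError("wavelength and distance must be positive")
    if sigma_um <= 0:
        raise ValueError("source size must be positive")
    return wavelength_A * 1e-10 * R_m / (sigma_um * 1e-6) * 1e6


def is_coherent(geometry: BeamlineGeometry, wavelength_A: float,
                sigma_um: float) -> bool:
    """True when the coherence length at the sample exceeds the Fresnel
    feature scale sqrt(λ·D), the condition for visible propagation fringes."""
    l_t = coherence_length(wavelength_A, geometry.l, sigma_um)
    feature = np.sqrt(wavelength_A * 1e-10 * geometry.D) * 1e6  # μm
    return bool(l_t > feature)


# ---------------------------------------------------------------------------
# refractive-index decrement ↔ electron density
# ---------------------------------------------------------------------------

def delta_to_electron_density(delta: float, wavelength_A: float) -> float:
    """n_e = 2πδ/(r_e λ²) in cm⁻³ (δ dimensionless, λ in Å).

    The far-from-edge relation between the real refractive-index decrement
    and the electron density; it is what makes the reconstructed grey values
    absolute densities.  Negative δ yields negative density — clipping is the
    caller's decision.
    """
    if np.any(np.asarray(wavelength_A) <= 0):
        raise ValueError("wavelength must be positive")
    lam = np.asarray(wavelength_A, dtype=float) * 1e-10
    n_si = 2 * np.pi * np.asarray(delta, dtype=float) / (CONSTANTS.r_e * lam**2)
    out = n_si * 1e-6  # m⁻³ → cm⁻³
    return out if np.ndim(out) else float(out)


def electron_density_to_delta(n_e: float, wavelength_A: float) -> float:
    """Inverse of :func:`delta_to_electron_density` (n_e in cm⁻³, λ in Å)."""
    if np.any(np.asarray(wavelength_A) <= 0):
        raise ValueError("wavelength must be positive")
    lam = np.asarray(wavelength_A, dtype=float) * 1e-10
    out = np.asarray(n_e, dtype=float) * 1e6 * CONSTANTS.r_e * lam**2 / (2 * np.pi)
    return out if np.ndim(out) else float(out)
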