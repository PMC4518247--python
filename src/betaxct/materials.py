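"""Material X-ray optics: δ(E), β(E), μ(E) for single-material samples.

A :class:`MaterialOptics` carries everything the single-material constraint
needs: the refractive-index decrement δ(E) (computed exactly from the
material electron density, valid away from absorption edges), the linear
absorption coefficient μ(E) interpolated log-log from a tabulated mass
attenuation grid, and β(E) = μλ/4π.

Small built-in demo tables (1–20 keV) are shipped for aluminium, tungsten
and a chitin-like biopolymer at ρ = 2.2 g/cm³ so the whole pipeline runs
without external data; measured tables remain a pluggable CSV input via
:meth:`MaterialOptics.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .physics import CONSTANTS, electron_density_to_delta, energy_to_wavelength

# Z and molar mass (g/mol) for the elements the demo materials need.
_ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Al": (13, 26.982), "Si": (14, 28.085), "W": (74, 183.84),
}


def electron_density(density_g_cm3: float, composition: dict[str, int]) -> float:
    """Electron density (cm⁻³) of a compound from ρ and its stoichiometry."""
    z_total = sum(n * _ELEMENTS[el][0] for el, n in composition.items())
    molar = sum(n * _ELEMENTS[el][1] for el, n in composition.items())
    return density_g_cm3 * Avogadro * z_total / molar


@dataclass(frozen=True)
class MaterialOptics:
    """Energy-dependent optical constants of one material.

    Attributes
    ----------
    name : str
    density : float
        Mass density, g/cm³.
    n_e : float
        Electron density, cm⁻³.
    table_energies : ndarray
        Tabulation grid, keV, strictly increasing.
    mu_rho_table : ndarray
        Mass attenuation coefficient μ/ρ on the grid, cm²/g.
    delta_table : ndarray or None
        Optional tabulated δ(E); if absent δ is computed from ``n_e``.
    """

    name: str
    density: float
    n_e: float
    table_energies: np.ndarray
    mu_rho_table: np.ndarray
    delta_table: np.ndarray | None = None

    def __post_init__(self):
        e = np.asarray(self.table_energies, float)
        m = np.asarray(self.mu_rho_table, float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing, length >= 2")
        if np.any(m < 0):
            raise ValueError("mass attenuation must be non-negative")
        object.__setattr__(self, "table_energies", e)
        object.__setattr__(self, "mu_rho_table", m)

    # -- interpolation ------------------------------------------------------
    def _check_support(self, energy_keV):
        e = np.atleast_1d(np.asarray(energy_keV, float))
        lo, hi = self.table_energies[0], self.table_energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"{self.name}: optics table supports {lo:g}-{hi:g} keV, "
                f"requested {e.min():g}-{e.max():g} keV")
        return e

    def mu(self, energy_keV):
        """Linear absorption coefficient μ(E) in cm⁻¹ (log-log interpolation)."""
        e = self._check_support(energy_keV)
        logmu = np.interp(np.log(e), np.log(self.table_energies),
                          np.log(self.mu_rho_table))
        out = np.exp(logmu) * self.density
        return out if np.ndim(energy_keV) else float(out[0])

    def delta(self, energy_keV):
        """Refractive-index decrement δ(E)."""
        e = self._check_support(energy_keV)
        if self.delta_table is not None:
            out = np.exp(np.interp(np.log(e), np.log(self.table_energies),
                                   np.log(self.delta_table)))
        else:
            out = electron_density_to_delta(self.n_e, energy_to_wavelength(e))
        return out if np.ndim(energy_keV) else float(out[0])

    def beta(self, energy_keV):
        """Imaginary part β(E) = μ(E)·λ(E)/4π of the refractive index."""
        e = self._check_support(energy_keV)
        lam_cm = energy_to_wavelength(e) * 1e-8
        out = self.mu(e) * lam_cm / (4 * np.pi)
        return out if np.ndim(energy_keV) else float(out[0])

    def delta_beta_ratio(self, energy_keV):
        return self.delta(energy_keV) / self.beta(energy_keV)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_csv(cls, path, name: str, density: float,
                 composition: dict[str, int] | None = None) -> "MaterialOptics":
        """Load a table with columns energy_keV, mu_rho_cm2_g[, delta]."""
        df = pd.read_csv(path)
        n_e = electron_density(density, composition) if composition else np.nan
        return cls(name=name, density=density, n_e=n_e,
                   table_energies=df["energy_keV"].to_numpy(),
                   mu_rho_table=df["mu_rho_cm2_g"].to_numpy(),
                   delta_table=df["delta"].to_numpy() if "delta" in df else None)


# ---------------------------------------------------------------------------
# built-in demo tables, 1-20 keV
# ---------------------------------------------------------------------------
# Aluminium mass attenuation with its K edge at 1.56 keV; values follow the
# standard photoelectric E^-3 trend between anchor points.
_AL_E = np.array([1.0, 1.5, 1.55, 1.57, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0,
                  10.0, 15.0, 20.0])
_AL_MU_RHO = np.array([1185.0, 402.2, 362.1, 3957.0, 2263.0, 788.0, 360.5,
                       193.4, 115.3, 50.33, 26.23, 7.955, 3.442])

# Tungsten: strongly absorbing everywhere in-band; M edges (~1.8-2.8 keV)
# and the L3 edge near 10.2 keV give the non-monotone structure.
_W_E = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0,
                 10.3, 12.0, 15.0, 20.0])
_W_MU_RHO = np.array([3683.0, 2828.0, 3922.0, 3181.0, 2270.0, 1252.0, 720.0,
                      456.0, 221.0, 95.9, 230.0, 200.0, 139.0, 65.7])

# Silicon (CCD sensor material) with its K edge at 1.84 keV.
_SI_E = np.array([1.0, 1.5, 1.83, 1.85, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0,
                  10.0, 15.0, 20.0])
_SI_MU_RHO = np.array([1570.0, 535.0, 309.0, 3193.0, 2777.0, 978.4, 452.9,
                       245.0, 147.0, 64.68, 33.89, 10.34, 4.464])

# Chitin-like biopolymer (C8H13NO5, ρ=2.2 g/cm³): smooth low-Z attenuation,
# photoelectric power law plus a Compton floor.
_CHITIN_E = np.array([1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0,
                      10.0, 12.0, 15.0, 20.0])
_CHITIN_MU_RHO = np.array([3792.0, 1103.0, 458.0, 133.3, 55.7, 28.4, 16.4,
                           10.4, 7.05, 5.04, 3.76, 2.32, 1.36, 0.79])


def aluminium() -> MaterialOptics:
    return MaterialOptics("aluminium", 2.70,
                          electron_density(2.70, {"Al": 1}), _AL_E, _AL_MU_RHO)


def tungsten() -> MaterialOptics:
    return MaterialOptics("tungsten", 19.3,
                          electron_density(19.3, {"W": 1}), _W_E, _W_MU_RHO)


def silicon() -> MaterialOptics:
    return MaterialOptics("silicon", 2.33,
                          electron_density(2.33, {"Si": 1}), _SI_E, _SI_MU_RHO)


def chitin() -> MaterialOptics:
    """Chitin-like single material; n_e ≈ 7.0 × 10²³ cm⁻³ at ρ = 2.2 g/cm³."""
    return MaterialOptics("chitin", 2.2,
                          electron_density(2.2, {"C": 8, "H": 13, "N": 1, "O": 5}),
                          _CHITIN_E, _CHITIN_MU_RHO)


DEMO_MATERIALS = {"aluminium": aluminium, "tungsten": tungsten,
                  "silicon": silicon, "chitin": chitin}


def get_material(name: str) -> MaterialOptics:
    try:
        return DEMO_MATERIALS[name]()
    except KeyError:
        raise KeyError(f"unknown demo material {name!r}; "
                       f"available: {sorted(DEMO_MATERIALS)}") from None
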