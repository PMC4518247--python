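"""Discrete photon-energy spectra and the universal synchrotron shape.

The betatron continuum is modelled by the angle-integrated universal
synchrotron function S(x) = x ∫_x^∞ K_{5/3}(t) dt with x = E/E_c.  S peaks
at x ≈ 0.2858 and rolls over exponentially above the critical energy E_c.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.special import kv

from .materials import MaterialOptics


@dataclass(frozen=True)
class Spectrum:
    """Photon-energy histogram: strictly increasing grid + per-bin weights.

    Weights may be photon counts or normalized probabilities; operations
    treat them as relative bin contents on the fixed grid.
    """

    energies: np.ndarray          # keV, strictly increasing
    weights: np.ndarray           # >= 0
    critical_energy: float | None = None

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        w = np.asarray(self.weights, float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing, length >= 2")
        if w.shape != e.shape:
            raise ValueError("weights must match energy grid")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    def normalized(self) -> "Spectrum":
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return replace(self, weights=self.weights / total)

    def mean_energy(self, response=None) -> float:
        """Weight- (and optionally response-) averaged photon energy, keV."""
        w = self.weights * (response(self.energies) if response else 1.0)
        return float(np.sum(w * self.energies) / np.sum(w))

    def peak_energy(self) -> float:
        return float(self.energies[int(np.argmax(self.weights))])

    def to_csv(self, path) -> None:
        pd.DataFrame({"energy_keV": self.energies,
                      "weight": self.weights}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df["energy_keV"].to_numpy(), df["weight"].to_numpy())


# ---------------------------------------------------------------------------
# universal synchrotron function
# ---------------------------------------------------------------------------
_S_CACHE: CubicSpline | None = None


def _build_s_spline() -> CubicSpline:
    # G(x) = ∫_x^∞ K_{5/3}(t) dt, evaluated once by quadrature on a log grid
    # and reused through a cubic spline of log S(x).
    import warnings
    xs = np.logspace(-4, np.log10(60.0), 400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # K_{5/3} ~ t^(-5/3) near 0 is steep
        gs = np.array([quad(lambda t: kv(5.0 / 3.0, t), x, x + 80.0,
                            limit=200)[0] for x in xs])
    s = xs * gs
    return CubicSpline(np.log(xs), np.log(np.maximum(s, 1e-300)))


def synchrotron_function(x):
    """S(x) = x ∫_x^∞ K_{5/3}(t) dt for x > 0 (vectorized, spline-backed)."""
    global _S_CACHE
    if _S_CACHE is None:
        _S_CACHE = _build_s_spline()
    x = np.asarray(x, float)
    out = np.zeros_like(x)
    inside = (x > 1e-4) & (x < 60.0)
    out[inside] = np.exp(_S_CACHE(np.log(x[inside])))
    # below the spline range use the small-x asymptote S ~ 2.1495 x^{1/3}
    small = (x > 0) & (x <= 1e-4)
    out[small] = 2.1495 * x[small] ** (1.0 / 3.0)
    return out


def synchrotron_spectrum(E_c: float, energies) -> Spectrum:
    """Normalized synchrotron-like continuum with critical energy ``E_c`` keV."""
    if E_c <= 0:
        raise ValueError("critical energy must be positive")
    energies = np.asarray(energies, float)
    if np.any(energies <= 0):
        raise ValueError("energy grid must be positive")
    w = synchrotron_function(energies / E_c)
    return Spectrum(energies, w / w.sum(), critical_energy=float(E_c))


def filter_transmission(material: MaterialOptics, thickness_um: float,
                        spectrum: Spectrum) -> Spectrum:
    """Beer-Lambert attenuation of a spectrum by ``thickness_um`` of material.

    Stacking commutes and composes: filter(t1) ∘ filter(t2) == filter(t1+t2).
    """
    if thickness_um < 0:
        raise ValueError("filter thickness must be >= 0")
    t_cm = thickness_um * 1e-4
    trans = np.exp(-material.mu(spectrum.energies) * t_cm)
    return replace(spectrum, weights=spectrum.weights * trans)


def identity_response(energies):
    """Default detector response: unit quantum efficiency at all energies."""
    return np.ones_like(np.asarray(energies, float))


def ccd_response(depletion_um: float = 50.0, foil_um: float = 0.0,
                 energy_weighting: bool = True):
    """Parametric deep-depletion silicon CCD response, as a callable of keV.

    Quantum efficiency 1 − exp(−μ_Si(E)·t) of a depletion layer of
    ``depletion_um``; ``energy_weighting`` multiplies by E because an
    integrating CCD collects charge proportional to the deposited photon
    energy; ``foil_um`` folds in an aluminium window in front of the chip.
    """
    from .materials import aluminium, silicon
    si = silicon()
    al = aluminium() if foil_um > 0 else None

    def response(energies):
        e = np.asarray(energies, float)
        out = 1.0 - np.exp(-si.mu(e) * depletion_um * 1e-4)
        if energy_weighting:
            out = out * e
        if al is not None:
            out = out * np.exp(-al.mu(e) * foil_um * 1e-4)
        return out

    return response
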