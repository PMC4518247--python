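#!/usr/bin/env python
"""Analytic worked numbers of the beamline and plasma source.

Every quantity here follows in closed form from the experiment's printed
inputs: the imaging-arm distances, the detector pitch, the plasma density
and electron energy of the betatron-optimised operating point, and the
measured source size.  Writes results/worked_numbers.json.
"""

import json
from pathlib import Path

import numpy as np

import betaxct as bx

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tomo = bx.make_geometry(0.73, 1.99)
    wire = bx.make_geometry(0.26, 3.00)
    state = bx.PlasmaState(n_e=1.1e19, gamma=bx.gamma_from_energy(200.0),
                           r_beta=1.0)
    lam_peak = bx.energy_to_wavelength(4.9)

    numbers = {
        "magnification_tomography_arm": tomo.M,
        "defocusing_distance_m": tomo.D,
        "sample_plane_pixel_um": tomo.sample_plane_pixel(22.5),
        "magnification_wire_arm": wire.M,
        "wavelength_at_8p8_keV_A": bx.energy_to_wavelength(8.8),
        "plasma_wavelength_um": bx.plasma_wavelength(1.1e19),
        "betatron_frequency_rad_s": bx.betatron_frequency(state),
        "wiggler_parameter_at_1um": bx.wiggler_parameter(state),
        "critical_energy_keV": bx.critical_energy(state),
        "coherence_length_at_sample_um":
            bx.coherence_length(lam_peak, 0.73, 1.8),
        "fresnel_feature_scale_um":
            float(np.sqrt(lam_peak * 1e-10 * tomo.D) * 1e6),
        "coherent_imaging_regime": bx.is_coherent(tomo, lam_peak, 1.8),
        "photons_in_measured_circle": 1.2e9 * 1.35e-2,
        "chitin_electron_density_cm3": bx.chitin().n_e,
    }

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "worked_numbers.json"
    out.write_text(json.dumps(numbers, indent=2, sort_keys=True) + "\n")

    print("beamline: M = {magnification_tomography_arm:.2f}, "
          "D = {defocusing_distance_m:.3f} m, sample-plane pixel = "
          "{sample_plane_pixel_um:.2f} um".format(**numbers))
    print("plasma:   lambda_p = {plasma_wavelength_um:.2f} um, "
          "K = {wiggler_parameter_at_1um:.2f}, "
          "E_c = {critical_energy_keV:.2f} keV".format(**numbers))
    print("coherence: l_t = {coherence_length_at_sample_um:.0f} um vs "
          "feature scale {fresnel_feature_scale_um:.1f} um -> coherent = "
          "{coherent_imaging_regime}".format(**numbers))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
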