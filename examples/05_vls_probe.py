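"""Oxyhemoglobin from reflectance spectra and the cubic calibration.

Spectra on the 400-500 nm grid are regressed on melanin / HbO / Hb
absorption shapes; the HbO coefficient is mapped to percent concentration
(100% = 150 g/l dermal HbO) through a third-order polynomial calibrated
on forward-model spectra.
"""

import numpy as np

from facewave.vls import (
    calibrate_mapping, coefficients_to_concentration, default_basis,
    fit_spectrum, synthetic_reflectance,
)

basis = default_basis()

# calibrate the cubic mapping on forward-model spectra
train = np.linspace(0.0, 120.0, 9)
coefs = [fit_spectrum(synthetic_reflectance(c, basis), basis).hbo for c in train]
mapping = calibrate_mapping(train, coefs)
print(f"cubic mapping coefficients (high->low): {np.round(mapping.coeffs, 3)}")
print(f"training residual RMS: {mapping.residual_rms:.2e} %")

for true_c in (25.0, 50.0, 100.0):
    fit = fit_spectrum(synthetic_reflectance(true_c, basis), basis)
    rec = coefficients_to_concentration(fit, mapping)
    print(f"true {true_c:5.1f}% -> HbO coefficient {fit.hbo:.3f} "
          f"-> recovered {rec:5.1f}%")
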