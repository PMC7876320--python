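"""Point-probe oxyhemoglobin estimation from visible-light reflectance.

Reflectance spectra on a fixed 400-500 nm grid (10-nm steps, 11 points,
relative to a white standard) are converted to absorbance, -log R, and
regressed on the absorption spectra of melanin, oxyhemoglobin and
deoxyhemoglobin plus a constant (ordinary least squares).  The
oxyhemoglobin regression coefficient is then mapped to a concentration
percentage through a third-order polynomial calibrated against a forward
model; 100% corresponds to 150 g/l oxyhemoglobin in the dermis (blood
hematocrit 44%).

The chromophore basis shipped here is an *approximate* table assembled
from standard literature absorption-curve shapes (hemoglobin Soret bands,
power-law melanin), unit-normalised; regression coefficients are therefore
relative and acquire physical meaning only through the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bandphase import TimeSeries

__all__ = [
    "WAVELENGTHS_NM",
    "ReflectanceSpectrum",
    "ChromophoreBasis",
    "VLSFit",
    "CubicMapping",
    "default_basis",
    "fit_spectrum",
    "calibrate_mapping",
    "coefficients_to_concentration",
    "synthetic_reflectance",
    "trace_from_spectra",
    "HBO_100_PERCENT_G_PER_L",
]

#: Fixed acquisition grid: 400-500 nm in 10-nm intervals.
WAVELENGTHS_NM = np.arange(400, 501, 10)

#: Dermal oxyhemoglobin concentration defined as 100%.
HBO_100_PERCENT_G_PER_L = 150.0

# Approximate molar-extinction shapes on the 400-500 nm grid (synthetic
# stand-ins following standard literature curve shapes; unit-normalised
# below).  Oxyhemoglobin peaks near 414 nm (Soret), deoxyhemoglobin near
# 430 nm, melanin decays as a power law.
_HBO_RAW = np.array(
    [266232.0, 466840.0, 480360.0, 246072.0, 102580.0, 62816.0,
     44480.0, 33209.0, 26629.0, 23684.0, 20932.0]
)
_HB_RAW = np.array(
    [180000.0, 250000.0, 390000.0, 530000.0, 270000.0, 110000.0,
     70000.0, 45000.0, 32000.0, 25000.0, 20862.0]
)
_MEL_RAW = (WAVELENGTHS_NM / 500.0) ** -3.48


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Reflectance relative to the white standard on the 11-point grid."""

    reflectance: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reflectance", np.asarray(self.reflectance, dtype=float)
        )
        object.__setattr__(
            self, "wavelengths", np.asarray(self.wavelengths)
        )
        if self.reflectance.shape != (11,):
            raise ValueError("spectrum must have 11 samples (400-500 nm, 10 nm)")
        if np.any(self.reflectance <= 0):
            raise ValueError("reflectance must be positive")

    @property
    def absorbance(self) -> np.ndarray:
        return -np.log(self.reflectance)


@dataclass(frozen=True)
class ChromophoreBasis:
    """Absorption spectra of melanin, HbO and Hb on the 11-point grid."""

    melanin: np.ndarray
    hbo: np.ndarray
    hb: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())

    def __post_init__(self) -> None:
        for name in ("melanin", "hbo", "hb"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (11,):
                raise ValueError(f"{name} basis must have 11 samples")
            if np.any(v < 0):
                raise ValueError(f"{name} basis must be nonnegative")
        m = np.column_stack([self.melanin, self.hbo, self.hb])
        if np.linalg.matrix_rank(m) < 3:
            raise ValueError("basis spectra are linearly dependent on the grid")

    def design(self) -> np.ndarray:
        """Regression design matrix [melanin, hbo, hb, 1]."""
        return np.column_stack(
            [self.melanin, self.hbo, self.hb, np.ones(11)]
        )


def default_basis() -> ChromophoreBasis:
    """Unit-normalised approximate chromophore basis."""
    return ChromophoreBasis(
        melanin=_MEL_RAW / _MEL_RAW.max(),
        hbo=_HBO_RAW / _HBO_RAW.max(),
        hb=_HB_RAW / _HB_RAW.max(),
    )


@dataclass
class VLSFit:
    """Regression result: chromophore coefficients plus the constant term."""

    melanin: float
    hbo: float
    hb: float
    intercept: float
    hbo_percent: Optional[float] = None  # set once a mapping is applied

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.melanin, self.hbo, self.hb, self.intercept])


@dataclass(frozen=True)
class CubicMapping:
    """Third-order polynomial from HbO regression coefficient to percent."""

    coeffs: np.ndarray  # highest order first, as np.polyval expects
    residual_rms: float = 0.0
    domain: tuple[float, float] = (-np.inf, np.inf)

    def __call__(self, hbo_coefficient: float) -> float:
        return float(np.polyval(self.coeffs, hbo_coefficient))

    @classmethod
    def identity(cls) -> "CubicMapping":
        return cls(np.array([0.0, 0.0, 1.0, 0.0]))


def fit_spectrum(
    spec: ReflectanceSpectrum,
    basis: ChromophoreBasis,
    on_absorbance: bool = True,
) -> VLSFit:
    """Ordinary least squares of the spectrum on the chromophore basis.

    By default the regression runs on absorbance -log R, the Beer-Lambert
    linearisation under which chromophore contributions add; set
    ``on_absorbance=False`` to regress the raw reflectance instead.
    """
    if not np.array_equal(spec.wavelengths, basis.wavelengths):
        raise ValueError("spectrum and basis wavelength grids differ")
    y = spec.absorbance if on_absorbance else spec.reflectance
    design = basis.design()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return VLSFit(*coef)


def calibrate_mapping(
    concentrations: Sequence[float], hbo_coefficients: Sequence[float]
) -> CubicMapping:
    """Least-squares cubic from fitted HbO coefficients to true percent.

    Needs at least 4 training pairs spanning the concentration range of
    interest; stores the training residual RMS and domain.
    """
    conc = np.asarray(concentrations, dtype=float)
    coefs = np.asarray(hbo_coefficients, dtype=float)
    if conc.size != coefs.size:
        raise ValueError("training pairs must align")
    if conc.size < 4:
        raise ValueError("need at least 4 training pairs for a cubic")
    if np.ptp(coefs) == 0:
        raise ValueError("degenerate design: coefficients do not vary")
    poly = np.polyfit(coefs, conc, deg=3)
    resid = conc - np.polyval(poly, coefs)
    return CubicMapping(
        poly, float(np.sqrt(np.mean(resid**2))),
        (float(coefs.min()), float(coefs.max())),
    )


def coefficients_to_concentration(fit: VLSFit, mapping: CubicMapping) -> float:
    """Apply the calibrated third-order mapping to a regression fit."""
    if mapping is None:
        raise ValueError("mapping has not been calibrated")
    value = mapping(fit.hbo)
    fit.hbo_percent = value
    return value


def synthetic_reflectance(
    hbo_percent: float,
    basis: Optional[ChromophoreBasis] = None,
    melanin_amount: float = 0.4,
    hb_amount: float = 0.2,
    offset: float = 0.05,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ReflectanceSpectrum:
    """Beer-Lambert forward model with a mildly nonlinear HbO loading.

    The effective HbO absorbance loading grows slightly faster than
    linearly with concentration (crowding of absorbers along the optical
    path), which is what makes a third-order inverse mapping necessary:

        load(c) = 0.8 c/100 + 0.6 (c/100)^2
        R = exp(-(melanin_amount * M + load * HbO + hb_amount * Hb + offset))
    """
    basis = basis if basis is not None else default_basis()
    c = hbo_percent / 100.0
    load = 0.8 * c + 0.6 * c * c
    absorb = (
        melanin_amount * basis.melanin
        + load * basis.hbo
        + hb_amount * basis.hb
        + offset
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        absorb = absorb + rng.normal(0.0, noise_sd, absorb.shape)
    return ReflectanceSpectrum(np.exp(-absorb), basis.wavelengths)


def trace_from_spectra(
    reflectances: np.ndarray,
    sample_rate: float,
    basis: Optional[ChromophoreBasis] = None,
    mapping: Optional[CubicMapping] = None,
) -> TimeSeries:
    """HbO time series from a stack of spectra, shape (t, 11).

    Each timestamp's spectrum is regressed on the basis; the HbO
    coefficients (mapped to percent when a mapping is given) form the
    returned trace, directly consumable by the cycle-length estimator.
    """
    refl = np.asarray(reflectances, dtype=float)
    if refl.ndim != 2 or refl.shape[1] != 11:
        raise ValueError("reflectances must have shape (t, 11)")
    if np.any(refl <= 0):
        raise ValueError("reflectance must be positive")
    basis = basis if basis is not None else default_basis()
    design = basis.design()
    coefs, *_ = np.linalg.lstsq(design, -np.log(refl).T, rcond=None)
    hbo = coefs[1]
    if mapping is not None:
        hbo = np.polyval(mapping.coeffs, hbo)
    return TimeSeries(hbo, sample_rate)
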