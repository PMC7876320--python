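"""Band-limited signal extraction and instantaneous phase/amplitude.

The oscillations of interest live in narrow frequency bands: the heartbeat
pulse near 1 Hz and the spontaneous blood-volume (Mayer-wave / vasomotion)
oscillation near 0.1 Hz.  Filtering is performed in the discrete Fourier
domain with a hard spectral mask; instantaneous phase and amplitude come
from the analytic signal (Hilbert transform), computed by zeroing negative
frequencies and doubling the retained positive frequencies.

Phase convention: 0 degrees at the positive-going maximum of the cosine
component, increasing with time, reported in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .chromomap import HbOMapSequence

__all__ = [
    "TimeSeries",
    "Band",
    "HEARTBEAT_BAND",
    "SLOW_BAND",
    "CYCLE_BAND",
    "BandAnalyticField",
    "bandpass",
    "analytic",
    "analytic_field",
    "power_spectrum",
    "movie_frame_span",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : ndarray, shape (n,)
        Sample values.
    sample_rate : float
        Sampling rate in Hz.
    """

    values: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("TimeSeries requires a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.sample_rate


@dataclass(frozen=True)
class Band:
    """A pass band [f_lo, f_hi] in Hz (edges inclusive in the DFT mask)."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band ({self.f_lo}, {self.f_hi})")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: Heartbeat pulse band.
HEARTBEAT_BAND = Band(0.4, 1.6)
#: Band bracketing the ~0.1 Hz blood-volume oscillation (phase/amplitude maps).
SLOW_BAND = Band(0.04, 0.2)
#: Wide low-frequency band used before cycle-length estimation; spans the
#: endothelial (0.0095-0.021 Hz), neurogenic (0.021-0.052 Hz) and myogenic
#: (0.052-0.145 Hz) ranges while suppressing the heartbeat.
CYCLE_BAND = Band(0.0095, 0.20)


@dataclass
class BandAnalyticField:
    """Instantaneous phase (degrees, [0,360)) and amplitude for one band.

    ``phase`` and ``amplitude`` share a common shape with time on the first
    axis: (t,) for a single trace or (t, y, x) for a map sequence.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    band: Band
    sample_rate: float

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")


def _band_mask(n: int, sample_rate: float, band: Band) -> np.ndarray:
    """Boolean mask over rfft bins with |f| in [f_lo, f_hi] (inclusive)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    # tiny tolerance so bin-aligned band edges are reliably included
    tol = 1e-9 * sample_rate
    return (freqs >= band.f_lo - tol) & (freqs <= band.f_hi + tol)


def _check_band(ts_rate: float, band: Band) -> None:
    nyquist = ts_rate / 2.0
    if band.f_hi > nyquist * (1 + 1e-12):
        raise ValueError(
            f"band upper edge {band.f_hi} Hz exceeds Nyquist {nyquist} Hz"
        )


def bandpass(ts: TimeSeries, band: Band, window: str = "none") -> TimeSeries:
    """DFT-domain band-pass filter.

    The mean is removed, an optional Hamming taper applied, the DFT taken,
    bins with |f| outside [f_lo, f_hi] zeroed, and the inverse DFT returned.
    With ``window="hamming"`` the taper is *left in* the output (the literal
    window-then-filter order); the default ``"none"`` preserves amplitude
    across the whole record, which phase/amplitude maps require.
    """
    _check_band(ts.sample_rate, band)
    if window not in ("none", "hamming"):
        raise ValueError(f"unknown window {window!r}")
    x = ts.values - ts.values.mean()
    if window == "hamming":
        x = x * np.hamming(ts.n)
    mask = _band_mask(ts.n, ts.sample_rate, band)
    if not mask.any():
        raise ValueError(
            f"band ({band.f_lo}, {band.f_hi}) Hz retains no DFT bins at "
            f"n={ts.n}, fs={ts.sample_rate}"
        )
    spec = np.fft.rfft(x)
    spec[~mask] = 0.0
    return TimeSeries(np.fft.irfft(spec, n=ts.n), ts.sample_rate)


def _analytic_along_axis0(
    values: np.ndarray, sample_rate: float, band: Band
) -> np.ndarray:
    """Complex analytic signal of the band content, time on axis 0."""
    n = values.shape[0]
    x = values - values.mean(axis=0, keepdims=True)
    freqs = np.fft.fftfreq(n, d=1.0 / sample_rate)
    tol = 1e-9 * sample_rate
    keep = (freqs >= band.f_lo - tol) & (freqs <= band.f_hi + tol)
    spec = np.fft.fft(x, axis=0)
    h = np.zeros(n)
    h[keep] = 2.0  # positive in-band frequencies doubled, all else zeroed
    shape = (n,) + (1,) * (values.ndim - 1)
    return np.fft.ifft(spec * h.reshape(shape), axis=0)


def analytic(ts: TimeSeries, band: Band) -> BandAnalyticField:
    """Instantaneous phase and amplitude of the band-limited signal.

    Forms the analytic signal by zeroing negative-frequency bins and
    doubling the retained positive bins; phase is the complex argument in
    degrees mapped to [0, 360), amplitude the modulus (envelope).
    """
    _check_band(ts.sample_rate, band)
    if not _band_mask(ts.n, ts.sample_rate, band).any():
        raise ValueError("band retains no DFT bins")
    z = _analytic_along_axis0(ts.values[:, None], ts.sample_rate, band)[:, 0]
    phase = np.degrees(np.angle(z)) % 360.0
    return BandAnalyticField(phase, np.abs(z), band, ts.sample_rate)


def analytic_field(
    maps: "HbOMapSequence", band: Band, max_block_bytes: int = 256 * 2**20
) -> BandAnalyticField:
    """Pixelwise analytic signal of a concentration map sequence.

    Equivalent to calling :func:`analytic` on every pixel's trace, but
    processed in pixel blocks so the peak complex working set stays under
    ``max_block_bytes``.

    Raises
    ------
    ValueError
        If the record is shorter than two periods of the band's lower edge
        (phase is not meaningful on a fraction of a cycle).
    """
    conc = maps.concentration
    rate = maps.frame_rate
    _check_band(rate, band)
    nt = conc.shape[0]
    if band.f_lo > 0 and nt / rate < 2.0 / band.f_lo:
        raise ValueError(
            f"record of {nt / rate:.1f} s is shorter than 2/f_lo = "
            f"{2.0 / band.f_lo:.1f} s for band ({band.f_lo}, {band.f_hi}) Hz"
        )
    spatial = conc.shape[1:]
    flat = conc.reshape(nt, -1)
    npix = flat.shape[1]
    # complex spectra dominate: ~4 arrays of complex128 per block
    block = max(1, int(max_block_bytes / (nt * 16 * 4)))
    phase = np.empty((nt, npix))
    amp = np.empty((nt, npix))
    for start in range(0, npix, block):
        z = _analytic_along_axis0(flat[:, start : start + block], rate, band)
        phase[:, start : start + block] = np.degrees(np.angle(z)) % 360.0
        amp[:, start : start + block] = np.abs(z)
    return BandAnalyticField(
        phase.reshape((nt,) + spatial), amp.reshape((nt,) + spatial), band, rate
    )


def power_spectrum(ts: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-windowed periodogram.

    Returns ``(frequencies, power)`` with one-sided doubling and the power
    normalised by the window energy, so that ``power.sum()`` equals the mean
    square of the windowed mean-removed record divided by the mean square of
    the window (Parseval).
    """
    x = ts.values - ts.values.mean()
    w = np.hamming(ts.n)
    spec = np.fft.rfft(w * x)
    power = np.abs(spec) ** 2
    # one-sided doubling; DC always present, Nyquist bin only for even n
    power[1:] *= 2.0
    if ts.n % 2 == 0:
        power[-1] /= 2.0
    power /= ts.n * np.sum(w**2)
    freqs = np.fft.rfftfreq(ts.n, d=1.0 / ts.sample_rate)
    return freqs, power


def movie_frame_span(frame_interval_s: float, first: int, last: int) -> float:
    """Elapsed time between two 1-based frame numbers of a phase movie."""
    if last < first:
        raise ValueError("last frame precedes first")
    return frame_interval_s * (last - first)
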