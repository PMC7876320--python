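"""Cycle-length estimation from the autocorrelation profile.

The period of the ~0.1 Hz oscillation is read off the normalised
autocorrelation

    A(tau) = sum_t I(t) I(t - tau) / sum_t I(t)^2

computed on the low-frequency band-passed, mean-removed trace for lags
0..30 s.  Scanning from tau = 0, the first local minimum is tau1 (the
half-cycle) and the first local maximum after it is tau2 (the full cycle);
tau2 is accepted as the cycle length only if A(tau1) < 0 and A(tau2) > 0,
otherwise the cycle length is indeterminate.  Autocorrelation is preferred
over the spectral peak because its profile is smooth, which makes the
extremum search stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .bandphase import Band, CYCLE_BAND, TimeSeries, bandpass

__all__ = ["CycleLengthResult", "autocorrelation", "cycle_length"]

#: Default maximum lag (s) of the autocorrelation scan.
MAX_LAG_S = 30.0


@dataclass
class CycleLengthResult:
    """Outcome of the autocorrelation cycle-length rule.

    ``A`` holds the raw autocorrelation on ``lags`` (s).  ``tau1``/``tau2``
    are the qualifying half-/full-cycle lags (s) when found.
    ``cycle_length`` is tau2 refined by parabolic interpolation, or None
    when the verdict is indeterminate; ``verdict_reason`` explains why.
    """

    lags: np.ndarray
    A: np.ndarray
    tau1: Optional[float]
    tau2: Optional[float]
    cycle_length: Optional[float]
    verdict_reason: str  # ok | no_local_min | no_local_max |
    #                      sign_condition_failed | degenerate_input

    @property
    def determinate(self) -> bool:
        return self.cycle_length is not None


def autocorrelation(ts: TimeSeries, max_lag: float = MAX_LAG_S) -> tuple[np.ndarray, np.ndarray]:
    """Normalised linear (non-circular) autocorrelation on a lag grid.

    A(tau_k) = sum_{t>=k} I(t) I(t-k) / sum_t I(t)^2, with the lag grid
    step equal to the sampling interval and lags 0..max_lag inclusive.
    The numerator sums over the overlapping samples only; the denominator
    over the full record, so A(0) = 1.

    Returns ``(lags_s, A)``.
    """
    if ts.duration <= max_lag:
        raise ValueError(
            f"record of {ts.duration:.1f} s must exceed the {max_lag} s "
            "maximum lag"
        )
    x = ts.values
    denom = float(np.dot(x, x))
    n_lags = int(np.floor(max_lag * ts.sample_rate)) + 1
    if denom == 0.0:
        return np.arange(n_lags) / ts.sample_rate, np.zeros(n_lags)
    acf = np.empty(n_lags)
    acf[0] = denom
    for k in range(1, n_lags):
        acf[k] = np.dot(x[k:], x[:-k])
    lags = np.arange(n_lags) / ts.sample_rate
    return lags, acf / denom


def _first_extrema(a_smooth: np.ndarray) -> tuple[Optional[int], Optional[int]]:
    """Indices of the first strict local minimum and the first strict local
    maximum occurring after it; plateaus take the earliest lag."""

    def scan(start: int, minimum: bool) -> Optional[int]:
        i = start
        n = a_smooth.size
        while 0 < i < n - 1:
            left, mid = a_smooth[i - 1], a_smooth[i]
            drop = mid < left if minimum else mid > left
            if drop:
                j = i
                while j + 1 < n and a_smooth[j + 1] == mid:
                    j += 1  # flat plateau: earliest lag wins
                if j + 1 < n:
                    rises = a_smooth[j + 1] > mid if minimum else a_smooth[j + 1] < mid
                    if rises:
                        return i
                    i = j
            i += 1
        return None

    i_min = scan(1, minimum=True)
    if i_min is None:
        return None, None
    i_max = scan(i_min + 1, minimum=False)
    return i_min, i_max


def _parabolic_refine(lags: np.ndarray, a: np.ndarray, j: int) -> float:
    """Sub-sample vertex of the parabola through (j-1, j, j+1)."""
    if j <= 0 or j >= a.size - 1:
        return float(lags[j])
    y0, y1, y2 = a[j - 1], a[j], a[j + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(lags[j])
    delta = 0.5 * (y0 - y2) / denom
    step = lags[1] - lags[0]
    return float(lags[j] + np.clip(delta, -1, 1) * step)


def cycle_length(
    ts: TimeSeries,
    max_lag: float = MAX_LAG_S,
    band: Optional[Band] = None,
    smooth_samples: int = 3,
) -> CycleLengthResult:
    """Apply the tau1/tau2 autocorrelation rule to a trace.

    The trace is expected to be the low-frequency band-passed, mean-removed
    signal; pass ``band=CYCLE_BAND`` (0.0095-0.20 Hz) to apply the filter
    here.  Extremum detection runs on a 3-sample moving average of A (the
    profile is smooth, so minimal smoothing suffices); the sign conditions
    A(tau1) < 0 < A(tau2) are checked on the raw profile, and the reported
    cycle length refines tau2 by parabolic interpolation.
    """
    if band is not None:
        ts = bandpass(ts, band)
    x = ts.values - ts.values.mean()
    if not np.any(x):
        lags = np.arange(int(np.floor(max_lag * ts.sample_rate)) + 1) / ts.sample_rate
        return CycleLengthResult(
            lags, np.zeros_like(lags), None, None, None, "degenerate_input"
        )
    lags, a = autocorrelation(TimeSeries(x, ts.sample_rate), max_lag)
    a_smooth = ndimage.uniform_filter1d(a, smooth_samples, mode="nearest")
    i_min, i_max = _first_extrema(a_smooth)
    if i_min is None:
        return CycleLengthResult(lags, a, None, None, None, "no_local_min")
    tau1 = float(lags[i_min])
    if i_max is None:
        return CycleLengthResult(lags, a, tau1, None, None, "no_local_max")
    tau2 = float(lags[i_max])
    if not (a[i_min] < 0 and a[i_max] > 0):
        return CycleLengthResult(
            lags, a, tau1, tau2, None, "sign_condition_failed"
        )
    refined = _parabolic_refine(lags, a, i_max)
    return CycleLengthResult(lags, a, tau1, tau2, refined, "ok")
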