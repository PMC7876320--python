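"""Spatial phase velocity of the traveling blood-volume wave.

Two estimators are provided.  ``contour_distance`` + ``phase_velocity``
automate the manual procedure of measuring, on a single phase-map frame,
the distance along the propagation direction between the 90 and 180 degree
(or 90 and 270 degree) phase contours: a quarter (half) wavelength, which
multiplied by four (two) and divided by the temporal cycle length gives
the phase velocity.  ``phase_gradient_velocity`` is an independent
automated cross-check: a weighted least-squares plane fit to the unwrapped
phase map whose gradient magnitude |grad phi| (deg/mm) gives
c = 360 f / |grad phi|.

Also includes the Moens-Korteweg relation PWV = sqrt(E h / (2 r rho)) as a
utility for reasoning about wall-elasticity effects on propagation speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase

from .bandphase import BandAnalyticField

__all__ = [
    "PhaseVelocityEstimate",
    "VesselParams",
    "contour_distance",
    "phase_velocity",
    "phase_gradient_velocity",
    "moens_korteweg",
    "phase_synchrony_deg",
]

#: Wavelength multiplier per contour pair: 90-180 deg spans a quarter cycle,
#: 90-270 deg spans a half cycle.
_PAIR_FACTOR = {"90-180": 4.0, "90-270": 2.0}
_PAIR_SPAN = {"90-180": 90.0, "90-270": 180.0}


@dataclass
class PhaseVelocityEstimate:
    velocity: float  # mm/s
    wavelength: float  # mm, spatial distance of one cycle
    cycle_length_s: float  # s
    contour_pair: Optional[str] = None  # "90-180" | "90-270" | None (plane fit)
    measurement_line: Optional[tuple] = None  # ((r0,c0),(r1,c1))
    direction: Optional[tuple[float, float]] = None  # (dx, dy), plane fit only

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        expected = self.wavelength / self.cycle_length_s
        if not np.isclose(self.velocity, expected, rtol=1e-9):
            raise ValueError("velocity != wavelength / cycle_length")


@dataclass(frozen=True)
class VesselParams:
    """Vessel wall and blood parameters for the Moens-Korteweg relation."""

    E: float  # elastic modulus, Pa
    h: float  # wall thickness, m
    r: float  # radius, m
    rho: float  # blood density, kg/m^3

    def __post_init__(self) -> None:
        for name in ("E", "h", "r", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sample_line(
    frame: np.ndarray, p0: tuple[float, float], p1: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Values along the segment p0 -> p1 ((row, col) coords), linearly
    interpolated at ~1 sample per pixel; returns (arclength_px, values)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(length)) * 2 + 1, 9)
    fracs = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] + (p1 - p0)[:, None] * fracs
    vals = ndimage.map_coordinates(frame, coords, order=1, mode="nearest")
    return fracs * length, vals


def _unwrap_line_phase(
    phase_frame: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    monotone_tol: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped phase (deg) along a line, flipped to be increasing.

    Wrapped phase is interpolated circularly (through the unit phasor) to
    avoid seam artifacts, unwrapped along the line, and its orientation
    fixed by the sign of the median increment.  Raises if more than
    ``monotone_tol`` of the increments oppose the median direction by more
    than a small jitter allowance.
    """
    s_cos, cosv = _sample_line(np.cos(np.radians(phase_frame)), p0, p1)
    _, sinv = _sample_line(np.sin(np.radians(phase_frame)), p0, p1)
    phi = np.degrees(np.unwrap(np.arctan2(sinv, cosv)))
    diffs = np.diff(phi)
    med = np.median(diffs)
    if med == 0:
        raise ValueError("line not aligned with propagation: flat phase")
    if med < 0:
        phi = -phi
        diffs = -diffs
        med = -med
    bad = np.mean(diffs < -0.25 * med)
    if bad > monotone_tol:
        raise ValueError(
            "line not aligned with propagation: phase not monotone "
            f"({bad:.0%} of increments reverse)"
        )
    return s_cos, phi


def contour_distance(
    field: BandAnalyticField,
    frame: int,
    line: tuple[tuple[float, float], tuple[float, float]],
    pair: str = "90-180",
    pixel_pitch: float = 0.365,
    amplitude_floor: Optional[float] = None,
) -> float:
    """Distance (mm) between the 90 deg contour and its pair along a line.

    The line (pixel coordinates (row, col) start/end) should follow the
    propagation direction across a region whose amplitude exceeds
    ``amplitude_floor`` (default: the frame's median amplitude) — phase is
    meaningless where the band amplitude is negligible.  Phase is sampled
    with circular linear interpolation, unwrapped monotonically, and the
    crossings of 90 deg and the pair's second value located by inverse
    interpolation.
    """
    if pair not in _PAIR_FACTOR:
        raise ValueError(f"unknown contour pair {pair!r}")
    phase_frame = field.phase[frame]
    amp_frame = field.amplitude[frame]
    floor = float(np.median(amp_frame)) if amplitude_floor is None else amplitude_floor
    _, amp_on_line = _sample_line(amp_frame, *line)
    if np.median(amp_on_line) < floor:
        raise ValueError(
            "line lies in a low-amplitude region; phase is unreliable there"
        )
    s_px, phi = _unwrap_line_phase(phase_frame, *line)
    # first crossing of 90 deg (mod 360) at or after the line start
    phi90 = 90.0 + 360.0 * np.ceil((phi[0] - 90.0) / 360.0)
    phi_second = phi90 + _PAIR_SPAN[pair]
    if phi_second > phi[-1]:
        raise ValueError(
            f"contour pair {pair} not present on the line "
            f"(phase spans {phi[0]:.0f}..{phi[-1]:.0f} deg)"
        )
    s1 = float(np.interp(phi90, phi, s_px))
    s2 = float(np.interp(phi_second, phi, s_px))
    return (s2 - s1) * pixel_pitch


def phase_velocity(
    distance_mm: float, pair: str, cycle_length_s: float,
    measurement_line: Optional[tuple] = None,
) -> PhaseVelocityEstimate:
    """Phase velocity from a contour distance and a temporal cycle length.

    wavelength = 4 x distance (90-180 pair) or 2 x distance (90-270 pair);
    velocity = wavelength / cycle length.
    """
    if pair not in _PAIR_FACTOR:
        raise ValueError(f"unknown contour pair {pair!r}")
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    if cycle_length_s <= 0:
        raise ValueError("cycle length must be positive")
    wavelength = _PAIR_FACTOR[pair] * distance_mm
    return PhaseVelocityEstimate(
        velocity=wavelength / cycle_length_s,
        wavelength=wavelength,
        cycle_length_s=cycle_length_s,
        contour_pair=pair,
        measurement_line=measurement_line,
    )


def phase_gradient_velocity(
    field: BandAnalyticField,
    frame: int,
    frequency_hz: float,
    region: Optional[tuple[slice, slice]] = None,
    pixel_pitch: float = 0.365,
    amplitude_floor: Optional[float] = None,
    min_gradient_deg_per_mm: float = 1e-3,
) -> PhaseVelocityEstimate:
    """Phase velocity from a weighted plane fit to the unwrapped phase map.

    The frame's phase is unwrapped in 2-D, a plane fitted by least squares
    with amplitude-squared weights over ``region`` (default: whole frame),
    and the velocity taken as 360 * f / |grad phi| with the propagation
    direction along -grad phi (phase decreases downstream).

    Raises
    ------
    ValueError
        If the fitted gradient is below ``min_gradient_deg_per_mm``
        (a spatially synchronized field, e.g. the heartbeat band, has no
        measurable phase slope and hence no finite velocity).
    """
    region = region or (slice(None), slice(None))
    phase = field.phase[frame][region]
    amp = field.amplitude[frame][region]
    floor = float(np.median(field.amplitude[frame])) if amplitude_floor is None else amplitude_floor
    phi = np.degrees(unwrap_phase(np.radians(phase) - np.pi) + np.pi)
    rows, cols = phi.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    w = amp.ravel() ** 2
    mask = amp.ravel() >= min(floor, np.median(amp))
    design = np.column_stack(
        [np.ones(phi.size), xx.ravel() * pixel_pitch, yy.ravel() * pixel_pitch]
    )
    sw = np.sqrt(w[mask])
    coef, *_ = np.linalg.lstsq(design[mask] * sw[:, None], phi.ravel()[mask] * sw, rcond=None)
    gx, gy = coef[1], coef[2]  # deg/mm
    gmag = float(np.hypot(gx, gy))
    if gmag < min_gradient_deg_per_mm:
        raise ValueError(
            "phase map has no measurable gradient (spatially synchronized "
            "field); phase velocity is unbounded"
        )
    velocity = 360.0 * frequency_hz / gmag
    wavelength = 360.0 / gmag
    return PhaseVelocityEstimate(
        velocity=velocity,
        wavelength=wavelength,
        cycle_length_s=1.0 / frequency_hz,
        contour_pair=None,
        direction=(-gx / gmag, -gy / gmag),
    )


def phase_synchrony_deg(
    field: BandAnalyticField,
    frame_range: Optional[tuple[int, int]] = None,
    region: Optional[tuple[slice, slice]] = None,
) -> float:
    """Maximum pairwise time-averaged phase lag (deg) across pixels.

    Each pixel's mean offset from the spatial reference is the circular
    mean over frames of its instantaneous phase difference; the spread is
    the maximum pairwise difference of those offsets.  A spatially
    synchronized field (heartbeat band) gives a spread near zero; a
    traveling wave gives the full phase span across the patch.
    """
    region = region or (slice(None), slice(None))
    t0, t1 = frame_range or (0, field.phase.shape[0])
    phase = np.radians(field.phase[t0:t1, region[0], region[1]])
    ref = np.angle(
        np.exp(1j * phase.reshape(phase.shape[0], -1)).mean(axis=1)
    )
    z = np.exp(1j * (phase - ref[:, None, None])).mean(axis=0)
    offsets = np.degrees(np.angle(z))
    return float(offsets.max() - offsets.min())


def moens_korteweg(params: VesselParams) -> float:
    """Pulse wave velocity PWV = sqrt(E h / (2 r rho)) in m/s.

    A softer wall (smaller elastic modulus E) gives a slower wave, which is
    why low-frequency pressure variations — seen by viscoelastic vessels as
    a soft wall — can propagate orders of magnitude slower than the ~10 m/s
    heartbeat pulse.
    """
    return float(np.sqrt(params.E * params.h / (2.0 * params.r * params.rho)))
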