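"""RGB video to relative oxyhemoglobin-concentration maps.

The chain is: per-frame gray-card illuminance correction, 3x3 spatial
averaging plus frame-rate halving (noise/data reduction), device RGB ->
XYZ through a calibration matrix M1, and a log-linear estimator

    C = a ln X + b ln Y + c ln Z + d

whose four coefficients (the vector ``M2p``) were calibrated against
tissue-optics simulations.  Only the *temporal variation* of C is
contractually meaningful: a pixel-wise multiplicative illuminance error k
scales all tristimulus values equally and shifts C by the time constant
(a+b+c) ln k, leaving C(t) - mean_t C(t) unchanged.  Units are nominally
ml oxyhemoglobin / 100 ml tissue, relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .bandphase import TimeSeries

__all__ = [
    "RGBVideo",
    "CalibrationMatrices",
    "HbOMapSequence",
    "ROISpec",
    "SRGB_TO_XYZ",
    "DEFAULT_M2P",
    "correct_illuminance",
    "preprocess",
    "rgb_to_xyz",
    "estimate_hbo",
    "roi_trace",
]

#: Linear sRGB (D65) -> XYZ matrix, shipped as the default M1 stand-in for a
#: camera matrix fitted to a color chart.  M1 cancels out of round-trip tests
#: that render through its inverse.
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: Default coefficients (a, b, c, d) of the log-linear concentration estimator.
DEFAULT_M2P = np.array([11.13525, -10.0444, -0.33082, -2.57943])


def _display_rate(rate: float) -> float:
    """Frame rate rounded half-up to 2 decimals (23.77/2 -> 11.89)."""
    return float(Decimal(repr(rate)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class RGBVideo:
    """Time-ordered RGB frames with 8-bit count scaling.

    ``frames`` has shape (t, y, x, 3); dtype may be uint8 (camera output) or
    float with values on the same 0..255 count scale (intermediate stages).
    ``graycard_region`` is a rectangle (row0, row1, col0, col1) (half-open)
    covering the reflectance-reference card, if present in the scene.
    """

    frames: np.ndarray
    frame_rate: float
    graycard_region: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (t, y, x, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("video needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frames.dtype == np.uint8:
            pass  # by construction in [0, 255]
        else:
            lo, hi = float(self.frames.min()), float(self.frames.max())
            if lo < -1e-9 or hi > 255 + 1e-9:
                raise ValueError("float frames must stay on the 0..255 scale")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


@dataclass
class CalibrationMatrices:
    """Device calibration: RGB->XYZ matrix M1 and estimator vector M2p."""

    M1: np.ndarray = field(default_factory=lambda: SRGB_TO_XYZ.copy())
    M2p: np.ndarray = field(default_factory=lambda: DEFAULT_M2P.copy())

    def __post_init__(self) -> None:
        self.M1 = np.asarray(self.M1, dtype=float)
        self.M2p = np.asarray(self.M2p, dtype=float)
        if self.M1.shape != (3, 3):
            raise ValueError("M1 must be 3x3")
        if self.M2p.shape != (4,):
            raise ValueError("M2p must be a 4-vector")
        if not np.all(np.isfinite(self.M2p)):
            raise ValueError("M2p must be finite")
        if abs(np.linalg.det(self.M1)) < 1e-12:
            raise ValueError("M1 is not invertible")

    @property
    def M1_inv(self) -> np.ndarray:
        return np.linalg.inv(self.M1)

    def to_file(self, path: str | Path) -> None:
        """Write as a plain-text 4x4 block: M1 in the top-left 3x3 (fourth
        column zero), M2p as the last row."""
        arr = np.zeros((4, 4))
        arr[:3, :3] = self.M1
        arr[3] = self.M2p
        np.savetxt(path, arr, fmt="%.10g")

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationMatrices":
        arr = np.loadtxt(path)
        if arr.shape != (4, 4):
            raise ValueError("calibration file must hold a 4x4 block")
        return cls(M1=arr[:3, :3], M2p=arr[3])


@dataclass
class HbOMapSequence:
    """Per-pixel relative oxyhemoglobin concentration over time.

    ``concentration`` has shape (t, y, x); invalid pixels (non-positive
    tristimulus input) are NaN.  ``frame_rate`` is the rate after any
    halving; ``frame_rate_display`` rounds it half-up to two decimals as it
    would be quoted (11.885 -> 11.89).
    """

    concentration: np.ndarray
    frame_rate: float
    pixel_pitch: Optional[float] = None  # mm / pixel, if known

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim != 3:
            raise ValueError("concentration must have shape (t, y, x)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def frame_rate_display(self) -> float:
        return _display_rate(self.frame_rate)

    @property
    def n_invalid(self) -> int:
        return int(np.isnan(self.concentration).sum())


@dataclass(frozen=True)
class ROISpec:
    """A fixed rectangular region of interest, identical in every frame."""

    top_left: tuple[int, int]  # (row, col)
    size: tuple[int, int] = (20, 20)  # (rows, cols)

    def physical_size_mm(self, pixel_pitch: float) -> tuple[float, float]:
        """Edge lengths in mm for a given pixel pitch (20 px @ 0.365 -> 7.3)."""
        return (self.size[0] * pixel_pitch, self.size[1] * pixel_pitch)

    def slices(self) -> tuple[slice, slice]:
        r, c = self.top_left
        return slice(r, r + self.size[0]), slice(c, c + self.size[1])


def correct_illuminance(video: RGBVideo) -> RGBVideo:
    """Per-frame, per-channel gray-card illuminance correction.

    Each frame's channels are divided by the ratio of that frame's gray-card
    mean to the first frame's gray-card mean, so the card's temporal mean
    becomes constant and any global illumination drift cancels.
    """
    if video.graycard_region is None:
        raise ValueError("video has no gray-card region; cannot correct")
    r0, r1, c0, c1 = video.graycard_region
    card = video.frames[:, r0:r1, c0:c1, :].astype(float)
    means = card.mean(axis=(1, 2))  # (t, 3)
    if np.any(means <= 0):
        raise ValueError("gray-card mean is zero in at least one frame/channel")
    gain = means / means[0]  # (t, 3)
    corrected = video.frames.astype(float) / gain[:, None, None, :]
    np.clip(corrected, 0.0, 255.0, out=corrected)
    return RGBVideo(corrected, video.frame_rate, video.graycard_region)


def preprocess(video: RGBVideo) -> RGBVideo:
    """3x3 spatial average per frame/channel, then frame-rate halving.

    Successive frame pairs (1,2), (3,4), ... are averaged pixel by pixel and
    channel by channel; an odd trailing frame is dropped.  Edge pixels of
    the box filter use replicate padding.  23.77 FPS input yields 11.885 FPS
    (displayed as 11.89).
    """
    frames = video.frames.astype(float)
    smoothed = ndimage.uniform_filter(frames, size=(1, 3, 3, 1), mode="nearest")
    n_pairs = smoothed.shape[0] // 2
    paired = 0.5 * (smoothed[0 : 2 * n_pairs : 2] + smoothed[1 : 2 * n_pairs : 2])
    region = video.graycard_region
    return RGBVideo(paired, video.frame_rate / 2.0, region)


def rgb_to_xyz(video: RGBVideo, calib: CalibrationMatrices) -> np.ndarray:
    """Map channels (scaled to [0,1] by /255) through M1 to XYZ.

    Returns an array of shape (t, y, x, 3).
    """
    rgb01 = video.frames.astype(float) / 255.0
    return np.einsum("ij,tyxj->tyxi", calib.M1, rgb01)


def estimate_hbo(
    xyz: np.ndarray,
    calib: CalibrationMatrices,
    frame_rate: float,
    pixel_pitch: Optional[float] = None,
) -> HbOMapSequence:
    """Log-linear concentration estimate C = a lnX + b lnY + c lnZ + d.

    Pixels with a non-positive tristimulus value at any time are flagged
    invalid (NaN) rather than clamped.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 4 or xyz.shape[-1] != 3:
        raise ValueError("xyz must have shape (t, y, x, 3)")
    a, b, c, d = calib.M2p
    invalid = np.any(xyz <= 0, axis=-1)
    safe = np.where(xyz > 0, xyz, 1.0)
    logs = np.log(safe)
    conc = a * logs[..., 0] + b * logs[..., 1] + c * logs[..., 2] + d
    conc[invalid] = np.nan
    return HbOMapSequence(conc, frame_rate, pixel_pitch)


def roi_trace(maps: HbOMapSequence, roi: ROISpec) -> TimeSeries:
    """Frame-by-frame mean concentration over a fixed rectangular ROI."""
    nrows, ncols = maps.concentration.shape[1:]
    r, c = roi.top_left
    if r < 0 or c < 0 or r + roi.size[0] > nrows or c + roi.size[1] > ncols:
        raise ValueError(
            f"ROI {roi.top_left}+{roi.size} falls outside frame ({nrows}, {ncols})"
        )
    rs, cs = roi.slices()
    values = maps.concentration[:, rs, cs].mean(axis=(1, 2))
    return TimeSeries(values, maps.frame_rate)
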