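"""Synthetic hemodynamic scenes with known ground truth.

Every downstream stage (concentration mapping, band phase extraction,
cycle-length estimation, phase-velocity measurement) is validated against
scenes generated here: a 2-D traveling sinusoidal oxyhemoglobin wave near
0.1 Hz with mm/s-scale phase velocity and optional episodic on/off epochs,
a spatially synchronized ~1 Hz heartbeat component, white concentration
noise, multiplicative illumination drift, a rendered gray-card strip, and
8-bit quantization.  Point-probe traces (10 Hz, flow- or concentration-
flavoured) carry the same oscillatory structure.

The renderer is the exact inverse of the concentration estimator: for a
target concentration C it picks XYZ on a monotone one-parameter family
(X, Z fixed at a skin-like anchor, Y solved from the log-linear estimator)
and maps XYZ back to 8-bit RGB through the inverse calibration matrix, so
estimator(render(C)) == C up to quantization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .bandphase import TimeSeries
from .chromomap import CalibrationMatrices, RGBVideo

__all__ = [
    "SceneConfig",
    "GroundTruthField",
    "GamutError",
    "generate_field",
    "render_rgb",
    "generate_probe_trace",
    "GRAYCARD_ROWS",
]

#: Height in pixels of the gray-card strip appended below the rendered skin
#: region (the physical card sits under the chin rest; exact geometry is
#: a rendering convention here).
GRAYCARD_ROWS = 10

#: Skin-like anchor in linear RGB (0..1) used by the forward optical model.
_ANCHOR_RGB = np.array([0.55, 0.45, 0.40])
_GRAYCARD_RGB = np.array([0.5, 0.5, 0.5])

#: Cosine taper length (s) applied at epoch edges so episodic on/off gating
#: does not splatter energy across the spectrum.
EPOCH_TAPER_S = 2.0


class GamutError(RuntimeError):
    """Raised when rendering would clip more than the allowed pixel fraction."""


@dataclass
class SceneConfig:
    """Ground-truth parameters of a synthetic scene.

    Defaults describe the nominal study conditions: a 0.1 Hz wave traveling
    at a few mm/s across a patch imaged at 23.77 FPS with 20 px = 7.3 mm
    (0.365 mm/px), plus a 1 Hz heartbeat synchronized across the patch.
    Amplitudes are in relative concentration units (ml/100 ml); they are
    free parameters chosen to give a clearly visible oscillation above a
    visible 8-bit noise floor.
    """

    grid_shape: tuple[int, int] = (60, 60)  # (rows, cols) of skin pixels
    pixel_pitch: float = 0.365  # mm / pixel
    frame_rate: float = 23.77  # Hz
    duration: float = 120.0  # s
    f_slow: float = 0.1  # Hz
    phase_velocity: float = 3.76  # mm/s
    direction: tuple[float, float] = (1.0, 0.0)  # unit (dx, dy) in col/row axes
    amp_slow: float = 0.5
    epochs: Optional[Sequence[tuple[float, float]]] = None  # None = always on
    f_heart: float = 1.0  # Hz
    amp_heart: float = 0.2
    baseline: float = 0.0
    noise_sd: float = 0.1
    illum_drift: Optional[Callable[[np.ndarray], np.ndarray]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_velocity <= 0:
            raise ValueError("phase_velocity must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if not (0 < self.f_slow < self.f_heart):
            raise ValueError("need 0 < f_slow < f_heart")
        if self.frame_rate <= 2 * self.f_heart:
            raise ValueError("frame_rate must exceed twice f_heart")
        if self.duration < 2.0 / self.f_slow:
            raise ValueError(
                f"duration {self.duration} s cannot express one slow cycle "
                f"(need >= {2.0 / self.f_slow} s)"
            )
        d = np.asarray(self.direction, dtype=float)
        norm = np.hypot(*d)
        if norm == 0:
            raise ValueError("direction must be a nonzero vector")
        self.direction = tuple(d / norm)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("illum_drift")  # callables are not serializable
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruthField:
    """Concentration field (t, y, x) with its known wave parameters."""

    concentration: np.ndarray
    true_cycle_length: float  # s
    true_phase_velocity: float  # mm/s
    config: SceneConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("concentration must be finite")


def _gate(times: np.ndarray, config: SceneConfig) -> np.ndarray:
    """On/off envelope of the slow wave with cosine-tapered epoch edges."""
    if config.epochs is None:
        return np.ones_like(times)
    g = np.zeros_like(times)
    taper = min(EPOCH_TAPER_S, *(0.5 * (e - s) for s, e in config.epochs))
    for start, stop in config.epochs:
        if stop <= start:
            raise ValueError(f"epoch ({start}, {stop}) has non-positive length")
        up = np.clip((times - start) / taper, 0.0, 1.0)
        down = np.clip((stop - times) / taper, 0.0, 1.0)
        ramp = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))
        ramp[(times < start) | (times > stop)] = 0.0
        g = np.maximum(g, ramp)
    return g


def _projection_mm(config: SceneConfig) -> np.ndarray:
    """Per-pixel position projected onto the propagation direction (mm)."""
    rows, cols = config.grid_shape
    y = np.arange(rows)[:, None] * config.pixel_pitch
    x = np.arange(cols)[None, :] * config.pixel_pitch
    dx, dy = config.direction
    return x * dx + y * dy


def generate_field(config: SceneConfig) -> GroundTruthField:
    """Render the ground-truth concentration movie.

    C(t, y, x) = baseline
               + gate(t) * amp_slow * sin(2 pi f_slow (t - proj(y,x)/c))
               + amp_heart * sin(2 pi f_heart t)        # no spatial lag
               + N(0, noise_sd)

    where proj is the pixel position (mm) projected on the propagation
    direction and c the phase velocity (mm/s).  The heartbeat term is
    synchronized across the patch.  Reproducible for a fixed seed.
    """
    t = config.times
    proj = _projection_mm(config)
    lag = proj / config.phase_velocity  # s
    slow = config.amp_slow * np.sin(
        2 * np.pi * config.f_slow * (t[:, None, None] - lag[None, :, :])
    )
    slow *= _gate(t, config)[:, None, None]
    heart = config.amp_heart * np.sin(2 * np.pi * config.f_heart * t)
    conc = config.baseline + slow + heart[:, None, None]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        conc = conc + rng.normal(0.0, config.noise_sd, conc.shape)
    return GroundTruthField(
        conc, 1.0 / config.f_slow, config.phase_velocity, config
    )


def _anchor_xyz(calib: CalibrationMatrices) -> np.ndarray:
    return calib.M1 @ _ANCHOR_RGB


def _xyz_for_concentration(
    conc: np.ndarray, calib: CalibrationMatrices
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monotone XYZ family with estimator(XYZ) == conc exactly.

    X and Z are pinned at the skin-like anchor; Y = Y0 exp((C - C0)/b)
    where C0 is the estimator value at the anchor and b the ln Y
    coefficient.
    """
    a, b, c, d = calib.M2p
    x0, y0, z0 = _anchor_xyz(calib)
    c0 = a * np.log(x0) + b * np.log(y0) + c * np.log(z0) + d
    y = y0 * np.exp((conc - c0) / b)
    return np.full_like(y, x0), y, np.full_like(y, z0)


def render_rgb(
    field: GroundTruthField,
    calib: CalibrationMatrices,
    config: Optional[SceneConfig] = None,
    quantize: bool = True,
    max_clip_fraction: float = 0.01,
) -> RGBVideo:
    """Render a concentration movie to 8-bit RGB through the forward model.

    A gray-card strip of :data:`GRAYCARD_ROWS` rows is appended below the
    skin region; the multiplicative illumination drift (if any) is applied
    to every channel of skin and card alike; RGB is obtained via the
    inverse of M1 and quantized to 8 bits.

    Raises
    ------
    GamutError
        If more than ``max_clip_fraction`` of channel samples fall outside
        [0, 255] before clipping.
    """
    config = config if config is not None else field.config
    if config is None:
        raise ValueError("a SceneConfig is required to render")
    conc = field.concentration
    nt, rows, cols = conc.shape
    t = np.arange(nt) / config.frame_rate
    drift = (
        np.asarray(config.illum_drift(t), dtype=float)
        if config.illum_drift is not None
        else np.ones(nt)
    )
    m1_inv = calib.M1_inv
    out = np.empty((nt, rows + GRAYCARD_ROWS, cols, 3))
    x, y, z = _xyz_for_concentration(conc, calib)
    xyz = np.stack([x, y, z], axis=-1)
    rgb01 = np.einsum("ij,tyxj->tyxi", m1_inv, xyz)
    out[:, :rows, :, :] = rgb01
    out[:, rows:, :, :] = _GRAYCARD_RGB
    out *= drift[:, None, None, None]
    counts = out * 255.0
    n_clipped = int(np.count_nonzero((counts < 0) | (counts > 255)))
    if n_clipped > max_clip_fraction * counts.size:
        raise GamutError(
            f"{n_clipped} of {counts.size} channel samples "
            f"({n_clipped / counts.size:.1%}) clip outside [0, 255]"
        )
    if quantize:
        frames = np.clip(np.rint(counts), 0, 255).astype(np.uint8)
    else:
        frames = np.clip(counts, 0.0, 255.0)
    card = (rows, rows + GRAYCARD_ROWS, 0, cols)
    return RGBVideo(frames, config.frame_rate, graycard_region=card)


def generate_probe_trace(
    config: SceneConfig, kind: str = "concentration", sample_rate: float = 10.0
) -> TimeSeries:
    """Point-probe time series with the scene's oscillatory structure.

    A 10 Hz trace: baseline + gated 0.1 Hz oscillation + 1 Hz pulse +
    white noise.  ``kind="flow"`` mimics a laser-Doppler flux channel
    (arbitrary flow units around a positive baseline, amplitudes scaled
    up); ``kind="concentration"`` mimics a reflectance-spectroscopy
    concentration channel in the scene's own units.
    """
    if kind not in ("flow", "concentration"):
        raise ValueError(f"unknown probe kind {kind!r}")
    n = int(round(config.duration * sample_rate))
    t = np.arange(n) / sample_rate
    gate = _gate(t, config)
    slow = config.amp_slow * np.sin(2 * np.pi * config.f_slow * t) * gate
    heart = config.amp_heart * np.sin(2 * np.pi * config.f_heart * t)
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    values = config.baseline + slow + heart + noise
    if kind == "flow":
        values = 30.0 + 10.0 * values  # flux units around a positive baseline
    return TimeSeries(values, sample_rate)


def save_ground_truth(field: GroundTruthField, path: str | Path) -> None:
    """JSON sidecar with the scene's true parameters (not the raster)."""
    payload = {
        "true_cycle_length_s": field.true_cycle_length,
        "true_phase_velocity_mm_s": field.true_phase_velocity,
        "config": json.loads(field.config.to_json()) if field.config else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
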