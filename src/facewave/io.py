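"""Reading and writing of videos, traces, spectra and analytic fields.

Videos travel either as uncompressed AVI (requires an ffmpeg-backed
imageio plugin) or as a numbered PNG sequence in a directory with a JSON
sidecar — the latter needs nothing beyond imageio's bundled PNG support
and is the format used throughout the test-suite.  Traces and spectra are
plain CSV; analytic fields are NumPy archives with a JSON metadata entry.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v2 as imageio
import numpy as np
import pandas as pd

from .bandphase import Band, BandAnalyticField, TimeSeries
from .chromomap import RGBVideo

__all__ = [
    "write_video",
    "read_video",
    "write_png_sequence",
    "read_png_sequence",
    "write_trace_csv",
    "read_trace_csv",
    "write_spectra_csv",
    "read_spectra_csv",
    "save_field",
    "load_field",
]

_SIDECAR = "video.json"


def write_png_sequence(video: RGBVideo, directory: str | Path) -> Path:
    """Numbered 8-bit PNG frames plus a JSON sidecar with the metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = video.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    for i, frame in enumerate(frames):
        imageio.imwrite(directory / f"frame_{i:05d}.png", frame)
    meta = {
        "frame_rate": video.frame_rate,
        "graycard_region": list(video.graycard_region)
        if video.graycard_region
        else None,
        "n_frames": int(frames.shape[0]),
    }
    (directory / _SIDECAR).write_text(json.dumps(meta, indent=2))
    return directory


def read_png_sequence(directory: str | Path) -> RGBVideo:
    directory = Path(directory)
    meta = json.loads((directory / _SIDECAR).read_text())
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    frames = np.stack([imageio.imread(p) for p in paths])
    region = meta.get("graycard_region")
    return RGBVideo(
        frames, meta["frame_rate"], tuple(region) if region else None
    )


def write_video(video: RGBVideo, path: str | Path) -> Path:
    """Write an AVI file (uncompressed) or, for a directory path or a path
    without an .avi suffix, a PNG sequence."""
    path = Path(path)
    if path.suffix.lower() != ".avi":
        return write_png_sequence(video, path)
    try:
        writer = imageio.get_writer(
            path, fps=video.frame_rate, codec="rawvideo", format="FFMPEG"
        )
    except Exception as exc:  # pragma: no cover - depends on ffmpeg plugin
        raise RuntimeError(
            "AVI output needs an ffmpeg-backed imageio plugin "
            "(pip install imageio-ffmpeg); use a directory path to write a "
            "PNG sequence instead"
        ) from exc
    frames = video.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    with writer:
        for frame in frames:
            writer.append_data(frame)
    meta_path = path.with_suffix(".json")
    meta = {
        "frame_rate": video.frame_rate,
        "graycard_region": list(video.graycard_region)
        if video.graycard_region
        else None,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return path


def read_video(
    path: str | Path, frame_rate: Optional[float] = None
) -> RGBVideo:
    """Read an AVI file or a PNG-sequence directory."""
    path = Path(path)
    if path.is_dir():
        return read_png_sequence(path)
    try:
        reader = imageio.get_reader(path, format="FFMPEG")
    except Exception as exc:  # pragma: no cover - depends on ffmpeg plugin
        raise RuntimeError(
            "AVI input needs an ffmpeg-backed imageio plugin "
            "(pip install imageio-ffmpeg)"
        ) from exc
    with reader:
        frames = np.stack([frame for frame in reader])
    sidecar = path.with_suffix(".json")
    region = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_rate = frame_rate or meta.get("frame_rate")
        region = meta.get("graycard_region")
    if frame_rate is None:
        raise ValueError("frame_rate not given and no JSON sidecar found")
    return RGBVideo(frames, frame_rate, tuple(region) if region else None)


def write_trace_csv(ts: TimeSeries, path: str | Path, value_name: str = "value") -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": ts.times, value_name: ts.values}).to_csv(
        path, index=False
    )
    return path


def read_trace_csv(path: str | Path) -> TimeSeries:
    """Read a (time_s, value) CSV; malformed rows are reported by number."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s,<value>")
    value_col = [c for c in df.columns if c != "time_s"][0]
    bad = df.index[
        df["time_s"].isna() | pd.to_numeric(df[value_col], errors="coerce").isna()
    ]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # 1-based + header
        raise ValueError(f"{path}: malformed values at row(s) {rows}")
    times = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(times)
    if steps.size == 0 or np.any(steps <= 0) or np.ptp(steps) > 1e-6 * steps[0]:
        raise ValueError(f"{path}: time_s must increase uniformly")
    return TimeSeries(df[value_col].to_numpy(dtype=float), 1.0 / steps[0])


def write_spectra_csv(
    reflectances: np.ndarray, sample_rate: float, path: str | Path
) -> Path:
    """Stack of spectra (t, 11) as CSV: time_s, r400, r410, ..., r500."""
    refl = np.asarray(reflectances, dtype=float)
    cols = {"time_s": np.arange(refl.shape[0]) / sample_rate}
    for i, wl in enumerate(range(400, 501, 10)):
        cols[f"r{wl}"] = refl[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)


def read_spectra_csv(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    wl_cols = [f"r{wl}" for wl in range(400, 501, 10)]
    missing = [c for c in wl_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing wavelength columns {missing}")
    times = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(times)
    if steps.size == 0 or np.any(steps <= 0):
        raise ValueError(f"{path}: time_s must increase")
    return df[wl_cols].to_numpy(dtype=float), 1.0 / steps[0]


def save_field(field: BandAnalyticField, path: str | Path) -> Path:
    """NumPy archive holding phase/amplitude and JSON metadata.

    Phase-map PNG rendering elsewhere uses the cyclic 'twilight' colormap;
    that choice is recorded here so the rasters stay interpretable.
    """
    meta = json.dumps(
        {
            "band_hz": [field.band.f_lo, field.band.f_hi],
            "sample_rate": field.sample_rate,
            "phase_units": "degrees in [0, 360)",
            "phase_colormap": "twilight (cyclic)",
        }
    )
    np.savez(
        path, phase=field.phase, amplitude=field.amplitude,
        meta=np.array(meta),
    )
    return Path(path)


def load_field(path: str | Path) -> BandAnalyticField:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return BandAnalyticField(
            data["phase"],
            data["amplitude"],
            Band(*meta["band_hz"]),
            meta["sample_rate"],
        )
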