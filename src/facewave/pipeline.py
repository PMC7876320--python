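"""End-to-end orchestration of the analysis stages.

``run_dci`` drives the camera branch: illuminance correction ->
3x3/frame-pair preprocessing -> RGB->XYZ -> concentration maps ->
slow- and heartbeat-band analytic fields -> ROI trace -> cycle length ->
phase velocity.  ``run_probe`` drives the point-probe branch: (spectra ->
HbO trace for VLS) -> low-frequency band filter -> cycle length.  All
outputs of a run land in one directory; summaries embed a hash of the
configuration and contain no timestamps, so reruns are bitwise identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from . import bandphase, chromomap, oscillometry, wavefield
from .bandphase import CYCLE_BAND, HEARTBEAT_BAND, SLOW_BAND, TimeSeries
from .chromomap import CalibrationMatrices, HbOMapSequence, RGBVideo, ROISpec
from . import vls as vls_mod

logger = logging.getLogger("facewave")

__all__ = ["RunConfig", "run_dci", "run_probe", "propose_roi"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run (paths resolved by the CLI)."""

    pixel_pitch: float = 0.365  # mm / pixel
    roi: Optional[ROISpec] = None  # None = auto-propose from slow-band amplitude
    line: Optional[tuple[tuple[float, float], tuple[float, float]]] = None
    contour_pair: str = "90-180"
    seed: int = 0
    outdir: Optional[Path] = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "pixel_pitch": self.pixel_pitch,
                "roi": [self.roi.top_left, self.roi.size] if self.roi else None,
                "line": self.line,
                "contour_pair": self.contour_pair,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def propose_roi(
    field: bandphase.BandAnalyticField, size: tuple[int, int] = (20, 20)
) -> ROISpec:
    """Highest-mean-amplitude window of the given size (helper; ROI
    placement is normally an explicit analyst choice)."""
    mean_amp = field.amplitude.mean(axis=0)
    size = (min(size[0], mean_amp.shape[0]), min(size[1], mean_amp.shape[1]))
    windowed = ndimage.uniform_filter(mean_amp, size=size, mode="constant")
    # valid window centers only
    half_r, half_c = size[0] // 2, size[1] // 2
    interior = windowed[
        half_r : mean_amp.shape[0] - (size[0] - half_r) + 1,
        half_c : mean_amp.shape[1] - (size[1] - half_c) + 1,
    ]
    r, c = np.unravel_index(np.argmax(interior), interior.shape)
    return ROISpec(top_left=(int(r), int(c)), size=size)


def _stage(name: str, **params) -> None:
    logger.info("stage=%s %s", name, json.dumps(params, default=str, sort_keys=True))


def run_dci(
    video: RGBVideo,
    calib: Optional[CalibrationMatrices] = None,
    config: Optional[RunConfig] = None,
) -> dict:
    """Run the full camera branch on a video; returns the result bundle.

    The bundle contains the concentration maps, both band fields, the ROI
    trace, the cycle-length result, phase-velocity estimates (plane-fit
    always; contour when a measurement line is configured or the default
    diagonal succeeds), and a JSON-ready summary.  If ``config.outdir`` is
    set, summary JSON / trace CSV / phase-map PNGs are written there.
    """
    calib = calib if calib is not None else CalibrationMatrices()
    config = config if config is not None else RunConfig()

    if video.graycard_region is not None:
        _stage("correct_illuminance", region=video.graycard_region)
        video = chromomap.correct_illuminance(video)
    else:
        _stage("correct_illuminance", skipped="no gray-card region")

    _stage("preprocess", input_fps=video.frame_rate)
    video = chromomap.preprocess(video)

    _stage("rgb_to_xyz")
    xyz = chromomap.rgb_to_xyz(video, calib)
    _stage("estimate_hbo", M2p=list(calib.M2p))
    maps = chromomap.estimate_hbo(
        xyz, calib, video.frame_rate, config.pixel_pitch
    )

    # exclude the gray-card strip (no hemodynamics there) from analysis
    if video.graycard_region is not None:
        r0 = video.graycard_region[0]
        maps = HbOMapSequence(
            maps.concentration[:, :r0, :], maps.frame_rate, maps.pixel_pitch
        )

    _stage("analytic_field", band="slow")
    slow = bandphase.analytic_field(maps, SLOW_BAND)
    _stage("analytic_field", band="heartbeat")
    heart = bandphase.analytic_field(maps, HEARTBEAT_BAND)

    roi = config.roi if config.roi is not None else propose_roi(slow)
    _stage("roi_trace", top_left=roi.top_left, size=roi.size)
    trace = chromomap.roi_trace(maps, roi)

    _stage("cycle_length", band=[CYCLE_BAND.f_lo, CYCLE_BAND.f_hi])
    cycle = oscillometry.cycle_length(trace, band=CYCLE_BAND)

    summary: dict = {
        "config_hash": config.config_hash(),
        "frame_rate_fps": maps.frame_rate_display,
        "roi": {"top_left": list(roi.top_left), "size": list(roi.size)},
        "cycle_length_s": cycle.cycle_length,
        "cycle_verdict": cycle.verdict_reason,
        "heartbeat_phase_spread_deg": wavefield.phase_synchrony_deg(heart),
    }

    velocity_grad = velocity_contour = None
    if cycle.determinate:
        f_est = 1.0 / cycle.cycle_length
        mid = slow.phase.shape[0] // 2
        try:
            velocity_grad = wavefield.phase_gradient_velocity(
                slow, mid, f_est, pixel_pitch=config.pixel_pitch
            )
        except ValueError as exc:
            summary["gradient_velocity_error"] = str(exc)
        velocity_contour = _contour_velocity(
            slow, cycle.cycle_length, config
        )
    else:
        _stage("phase_velocity", skipped="cycle length indeterminate")
    summary["phase_velocity_gradient_mm_s"] = (
        velocity_grad.velocity if velocity_grad else None
    )
    summary["phase_velocity_contour_mm_s"] = (
        velocity_contour.velocity if velocity_contour else None
    )

    bundle = {
        "maps": maps,
        "slow_field": slow,
        "heartbeat_field": heart,
        "roi_trace": trace,
        "cycle": cycle,
        "velocity_gradient": velocity_grad,
        "velocity_contour": velocity_contour,
        "summary": summary,
    }
    if config.outdir is not None:
        _write_bundle(bundle, config.outdir)
    return bundle


def _contour_velocity(
    slow: bandphase.BandAnalyticField,
    cycle_length_s: float,
    config: RunConfig,
) -> Optional[wavefield.PhaseVelocityEstimate]:
    """Median contour-based velocity over frames where the pair is visible."""
    rows, cols = slow.phase.shape[1:]
    line = config.line or ((1.0, 1.0), (rows - 2.0, cols - 2.0))
    _stage("contour_velocity", line=line, pair=config.contour_pair)
    velocities = []
    n_frames = slow.phase.shape[0]
    for frame in range(0, n_frames, max(1, n_frames // 48)):
        try:
            d = wavefield.contour_distance(
                slow, frame, line, config.contour_pair, config.pixel_pitch
            )
            est = wavefield.phase_velocity(
                d, config.contour_pair, cycle_length_s, line
            )
        except ValueError:
            continue
        velocities.append(est.velocity)
    if not velocities:
        return None
    med = float(np.median(velocities))
    return wavefield.phase_velocity(
        med * cycle_length_s / wavefield._PAIR_FACTOR[config.contour_pair],
        config.contour_pair,
        cycle_length_s,
        line,
    )


def run_probe(
    trace: Optional[TimeSeries] = None,
    spectra: Optional[np.ndarray] = None,
    sample_rate: Optional[float] = None,
    kind: str = "ldf",
    mapping: Optional[vls_mod.CubicMapping] = None,
    outdir: Optional[Path] = None,
) -> dict:
    """Run the point-probe branch (LDF-style trace or VLS spectra).

    For ``kind="vls"`` a stack of reflectance spectra (t, 11) is first
    converted to an HbO trace by per-timestamp regression; either way the
    trace is band-limited to 0.0095-0.20 Hz and the cycle length derived.
    """
    if kind == "vls":
        if spectra is None or sample_rate is None:
            raise ValueError("VLS run needs spectra and sample_rate")
        _stage("fit_spectra", n=int(np.asarray(spectra).shape[0]))
        trace = vls_mod.trace_from_spectra(spectra, sample_rate, mapping=mapping)
    elif kind != "ldf":
        raise ValueError(f"unknown probe kind {kind!r}")
    if trace is None:
        raise ValueError("LDF run needs a trace")
    if trace.duration <= oscillometry.MAX_LAG_S:
        raise ValueError(
            f"trace of {trace.duration:.1f} s is too short: the "
            f"autocorrelation scan needs more than {oscillometry.MAX_LAG_S} s"
        )
    _stage("cycle_length", band=[CYCLE_BAND.f_lo, CYCLE_BAND.f_hi])
    cycle = oscillometry.cycle_length(trace, band=CYCLE_BAND)
    summary = {
        "kind": kind,
        "duration_s": trace.duration,
        "cycle_length_s": cycle.cycle_length,
        "cycle_verdict": cycle.verdict_reason,
    }
    bundle = {"trace": trace, "cycle": cycle, "summary": summary}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        from .io import write_trace_csv

        write_trace_csv(trace, outdir / "trace.csv")
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .io import write_trace_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(
        json.dumps(bundle["summary"], indent=2, sort_keys=True)
    )
    write_trace_csv(bundle["roi_trace"], outdir / "roi_trace.csv", "hbo")
    for name in ("slow_field", "heartbeat_field"):
        fld = bundle[name]
        mid = fld.phase.shape[0] // 2
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(fld.phase[mid], cmap="twilight", vmin=0, vmax=360)
        ax.set_title(f"{name} phase (deg), mid frame")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(outdir / f"{name}_phase.png", dpi=100)
        plt.close(fig)
    cyc = bundle["cycle"]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(cyc.lags, cyc.A, color="k", lw=1)
    ax.axhline(0, color="gray", lw=0.5)
    if cyc.tau1 is not None:
        ax.axvline(cyc.tau1, color="tab:blue", ls="--", label=r"$\tau_1$")
    if cyc.tau2 is not None:
        ax.axvline(cyc.tau2, color="tab:red", ls="--", label=r"$\tau_2$")
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("A(lag)")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(outdir / "autocorrelation.png", dpi=100)
    plt.close(fig)
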