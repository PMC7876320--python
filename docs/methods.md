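# Methods

`facewave` analyses the spontaneous ~0.1 Hz oscillation of skin blood
volume (the Mayer-wave / vasomotion frequency range) as a *spatial* field:
instead of asking whether two probe sites oscillate in or out of phase, it
maps the instantaneous phase of the oscillation over a skin patch and
measures the speed at which constant-phase fronts travel across it. This
note records the models, the defaults and the design choices.

## Concentration estimation from RGB video

A camera frame is mapped to a relative oxyhemoglobin concentration per
pixel in four steps.

1. **Illuminance correction.** Each frame's channels are divided by the
   ratio of that frame's gray-card mean to the first frame's gray-card
   mean, per channel. Any illumination gain common to the scene and the
   card cancels exactly.
2. **Preprocessing.** A 3×3 box average per frame and channel (replicate
   padding at the edges), then frame pairs (1,2), (3,4), … are averaged
   and the frame rate halves; an odd trailing frame is dropped. At the
   nominal 23.77 FPS the output rate is 11.885 FPS, quoted as 11.89
   (decimal half-up rounding; binary round-half-even would misreport it
   as 11.88). Both signal bands survive essentially unattenuated: pair
   averaging scales a tone at f by cos(πf/fs), i.e. 0.9991 at 0.1 Hz and
   0.991 at 1 Hz.
3. **RGB → XYZ.** Channels are scaled to [0,1] by /255 and mapped through
   a 3×3 calibration matrix M1. The default M1 is the linear sRGB(D65)
   matrix; a camera-specific matrix fitted to a color chart can be
   supplied as a plain-text file. Any fixed channel scaling is absorbed
   by the estimator's offset property below.
4. **Log-linear estimator.** C = a·ln X + b·ln Y + c·ln Z + d with
   (a,b,c,d) = (11.13525, −10.0444, −0.33082, −2.57943). The form makes
   the estimator's key robustness property explicit: a multiplicative
   illuminance error k at a pixel scales X, Y, Z equally and shifts C by
   the time constant (a+b+c)·ln k, so the *temporal variation*
   C(t) − mean_t C(t) — the only quantity used downstream — is invariant
   to static per-pixel illuminance errors. Only temporal variation is
   contractually meaningful; absolute values are relative (nominal unit
   ml/100 ml). Non-positive tristimulus values mark a pixel invalid (NaN)
   rather than being clamped.

ROIs are fixed rectangles (default 20×20 px; at the default pitch of
0.365 mm/px that is 7.3×7.3 mm) averaged frame by frame.

## Band-limited phase and amplitude

Filtering is a hard mask in the DFT domain: remove the mean, transform,
zero all bins with |f| outside the band (edges inclusive), invert. Bands:
0.4–1.6 Hz (heartbeat), 0.04–0.2 Hz (the 0.1 Hz wave, used for phase and
amplitude maps), and 0.0095–0.20 Hz (cycle-length preparation; spans the
endothelial, neurogenic and myogenic vasomotion ranges while suppressing
the heartbeat). The analytic signal is formed by zeroing negative
frequencies and doubling the retained positive bins; its argument (degrees
in [0,360), zero at the cosine maximum, increasing in time) and modulus
are the instantaneous phase and amplitude. Per-pixel fields are processed
in pixel blocks under a configurable memory budget and are identical to
the single-trace path.

A Hamming taper is standard before a periodogram but attenuates record
edges if left in a reconstructed signal, which would corrupt amplitude
maps near the start and end of a recording. Default behaviour therefore
applies the window in `power_spectrum` only, and `bandpass`/`analytic`
default to `window="none"`; `bandpass(..., window="hamming")` reproduces
the literal window-then-filter-then-invert order for comparison.

## Cycle length

The period estimate uses the normalised linear autocorrelation
A(τ) = Σ_t I(t)I(t−τ) / Σ_t I(t)², numerator over overlapping samples,
denominator over the full record (A(0)=1), on lags 0…30 s with the lag
step equal to the sampling interval. Scanning from τ=0, τ1 is the first
strict local minimum and τ2 the first strict local maximum *after* τ1 —
a maximum occurring before any minimum cannot qualify. The estimate is
determinate iff A(τ1) < 0 and A(τ2) > 0; otherwise the result carries a
reason (`no_local_min`, `no_local_max`, `sign_condition_failed`,
`degenerate_input`). Numerical choices: extremum detection runs on a
3-sample moving average of A (the profile is smooth, so minimal smoothing
suffices; tie plateaus resolve to the earliest lag); the sign conditions
are checked on the raw profile; the reported cycle length refines τ2 by a
parabolic fit through the three raw samples around the discrete maximum,
with the vertex clamped to ±1 lag step. The input is expected to be the
0.0095–0.20 Hz filtered trace (`band=CYCLE_BAND` applies it in place).

## Phase velocity

Two estimators, kept deliberately independent:

- **Contour distances** (the field workflow, automated). On one phase-map
  frame, phase is sampled along a user- or default-chosen line by linear
  interpolation of the unit phasor (interpolating wrapped phase directly
  creates seam artifacts), unwrapped, and oriented by the sign of the
  median increment. The positions where the unwrapped phase crosses 90°
  and 180° (or 270°) are located by inverse interpolation; the distance,
  multiplied by 4 (quarter cycle) or 2 (half cycle) and converted by the
  pixel pitch, is the wavelength, and velocity = wavelength / cycle
  length. The line must lie where band amplitude exceeds a floor (default:
  the frame median) and must be monotone in phase, otherwise an error
  names the problem; a contour pair that does not fit on the line in a
  given frame is an error too, so callers typically scan frames and take
  the median of the successful measurements — the programmatic analogue of
  choosing a frame "depending on visibility".
- **Phase-plane gradient** (cross-check). The frame's phase is unwrapped
  in 2-D, a plane fitted by least squares with amplitude² weights, and
  velocity = 360°·f / |∇φ| with propagation along −∇φ (phase decreases
  downstream). A gradient below 10⁻³ deg/mm raises an error: a spatially
  synchronized field (the heartbeat band) has no finite measurable
  velocity.

Spatial synchrony itself is quantified by `phase_synchrony_deg`: per
pixel, the circular mean over frames of the phase offset from the spatial
reference, then the maximum pairwise spread of those offsets. Averaging
over frames is what makes a <5° criterion meaningful in the presence of
per-frame noise jitter.

The cycle length used for a velocity estimate is taken from the ROI trace
nearest the measurement line (site-local rather than global).

`moens_korteweg` evaluates PWV = √(E·h/(2·r·ρ)) — the standard relation
between pulse wave velocity and wall elasticity — as a utility for the
physical argument that viscoelastic walls, soft at 0.1 Hz, would carry a
slow wave even if the oscillation originates centrally.

## VLS point probe

Reflectance spectra (400–500 nm, 10-nm grid, relative to a white
standard) are converted to absorbance −ln R and regressed by OLS on
melanin, oxyhemoglobin and deoxyhemoglobin absorption shapes plus an
intercept. Absorbance is the Beer–Lambert linearisation under which
chromophore contributions add; a raw-reflectance mode is retained behind
a flag. The shipped basis is an *approximate, synthetic* table following
standard literature curve shapes (hemoglobin Soret bands near 414/430 nm,
power-law melanin), unit-normalised; coefficients are therefore relative.
The HbO coefficient maps to percent concentration (100% ≡ 150 g/l dermal
HbO) through a third-order polynomial calibrated by least squares on ≥4
forward-model pairs; the package's forward model adds a mild quadratic
nonlinearity to the HbO loading so the cubic inverse is exercised. The
mapping's input is the single HbO coefficient by default (configurable).

## Synthetic scenes: what they emulate and what they do not

The generator produces C(t,y,x) = baseline + gate(t)·A_s·sin(2πf_s(t −
r·û/c)) + A_h·sin(2πf_h t) + N(0,σ²): a plane wave at f_s = 0.1 Hz
traveling at c mm/s along û, a heartbeat at f_h = 1 Hz with *no* spatial
lag (a ~10 m/s pulse crosses a face in well under one frame), optional
episodic on/off epochs with a 2 s cosine taper (the oscillation is known
to emerge and vanish; the taper shape is a modelling choice to avoid
spectral splatter), and white concentration noise. Defaults: 60×60 px at
0.365 mm/px, 23.77 FPS, c = 3.76 mm/s, A_s = 0.5, A_h = 0.2, σ = 0.1
(relative ml/100 ml units; the amplitude scale is a free parameter chosen
once to give a clearly visible oscillation above a visible noise floor),
epochs off (continuous oscillation — episodic gating is exercised
explicitly where it is the property under test). Probe traces are 10 Hz
with the same structure; the flow flavour rescales to a positive baseline.

Rendering inverts the estimator: X and Z are pinned at a skin-like anchor
and Y = Y₀·exp((C−C₀)/b), a family monotone in C on which the estimator
returns C exactly; XYZ maps to RGB via M1⁻¹, an optional multiplicative
illumination drift is applied to all channels including a 10-row gray-card
strip appended below the patch, and frames are quantized to 8 bits (counts
outside [0,255] above a 1% budget raise a gamut error). Because the
forward model is the estimator's inverse by construction, round-trip tests
validate the estimator's *properties* (offset structure, drift
cancellation, quantization floor), not the physiological accuracy of the
coefficient values — those are taken as given, with the underlying
radiative-transport modelling out of scope. Likewise absent from the
scenes: face geometry and curvature, motion, spatially varying melanin,
and physiological frequency drift. Passing recovery tests therefore show
the *analysis chain* is correct and unbiased at realistic SNR, not that
the camera calibration is accurate on real skin.

## Problem sizes and numerical tolerances

Recovery studies use 60×60 px, 120 s scenes (≈2850 rendered frames) and
900 s probe traces — large enough that band filters resolve 0.1 Hz with
df ≤ 0.01 Hz while keeping a full test run in tens of seconds. Oracle
equivalences are asserted at 10⁻¹² (autocorrelation vs direct double
loop; regression vs normal equations) and 10⁻¹⁰ (band-pass vs explicit
bin projection). The gain-invariance property is asserted at 10⁻⁹ on
values of order 10: logarithms of gained tristimulus values are not
bitwise equal to shifted logarithms, so "machine precision" here means
rounding-error accumulation, not bit identity. Band edges are inclusive
with a 10⁻⁹·fs tolerance so bin-aligned tones pass exactly.

## Known limitations

- AVI I/O requires an ffmpeg-backed imageio plugin; without one, the PNG
  sequence + JSON sidecar format provides the same contract.
- The contour estimator requires the contour pair to fit on the line: at
  c = 8 mm/s the quarter wavelength is 20 mm, so a 60-px patch must be
  measured along its 31 mm diagonal and only a minority of frames are
  measurable — mirroring the visibility constraint of the manual
  procedure.
- The cycle-length rule reports whatever qualifying extremum pair exists;
  on structureless band-limited noise it can return a "determinate" but
  physiologically meaningless value. Verdicts are rule outcomes, not
  significance statements.
- The VLS basis and forward model are synthetic; VLS percent values are
  internally consistent, not traceable to tissue optics.
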