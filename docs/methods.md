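# Methods

This note documents the models, estimators and numerical choices behind
`rotormap`, in the order data flows through the pipeline.

## 1. Synthetic excitable medium

**Model.** The ground-truth generator integrates the Aliev–Panfilov
two-variable monodomain system,

    ∂u/∂t′ = D′∇²u − k·u(u − a)(u − 1) − u·v
    ∂v/∂t′ = (ε₀ + μ₁ v/(u + μ₂)) · (−v − k·u(u − a − 1)),

with excitation variable u ∈ [0, 1], recovery variable v, and no-flux
(mirrored) boundaries matching the edge of a cultured monolayer. One
dimensionless time unit is `time_scale_ms` = 12.9 ms, the conventional
scaling for this model; diffusion (mm²/ms) and pixel pitch `dx` (mm/px)
convert to per-pixel units as D′ = diffusion · time_scale_ms / dx².

**Defaults and why.** k = 8, a = 0.1, ε₀ = 0.002, μ₁ = 0.2, μ₂ = 0.3,
diffusion = 0.1 mm²/ms, dx = 1 mm/px, dt_sim = 0.5 ms on a 128 × 128
grid. This set was chosen once for three properties verified by the test
suite: a planar wave propagates at a stable speed following the √D law
(≈13 cm/s at default D); the action potential lasts ≈490 ms, so rotors
rotate at ≈2.7 Hz — inside the 1–30 Hz analysis band; and a cross-field
S2 delivered 850 ms after S1 (into the repolarisation tail as it crosses
mid-field) creates a single stable spiral whose tip stays >10 px from
the boundary for tens of seconds. Forward Euler requires
dt_sim ≤ dx²/(4·diffusion); the bound is enforced at construction.

**Stimuli.** `planar_s1` (repeated edge-strip pulses; 10 Hz burst pacing
for 30 s is period_ms = 100, count = 300), `cross_field_s2` (planar S1,
then one half-field S2 after `s2_offset_ms`), `point_burst` (central
square). Pulses set u = 1 in the region for 2 ms.

**Ground truth.** During integration the simulator records, per pixel
and beat, the upward crossing of u = 0.5 (activation, linearly
interpolated between steps) and the time to fall below 1 − f (APD at
fraction f). For planar S1 runs, conduction velocity is the inverse
slope of activation time regressed on distance along the propagation
axis. Spiral tips are located post hoc by the isopotential-intersection
method: the u = 0.5 isolines at t and t − 20 ms (sub-pixel contours,
intersected as line strings) cross at the pivot of a rotating wave.
Tip chirality is the winding sign of the vector field
(u_t − ½, u_{t−δ} − ½) around the intersection, which provably matches
the sign of the local phase winding for narrow-band signals — so the
oracle and the phase detector share a sign convention without sharing
any code.

**Forward optics.** F = baseline + polarity · gain · u, an optional
mono-exponential bleaching envelope, additive white Gaussian noise per
pixel and frame, and nearest-frame decimation to the camera interval
(default 5 ms, i.e. 200 frames/s). Defaults are identity optics with 2%
noise in the verification scenarios; no published amplitude or noise
statistics exist for the recordings these emulate, so `noise_sd` is a
free parameter, not a calibrated value.

**Electrograms.** Each electrode reads the pixel nearest its grid
position: a biphasic derivative-of-Gaussian spike (σ = 2 ms) at the
local activation time with amplitude proportional to the local upstroke
slope, plus a low, broad Gaussian "T-wave" (σ = 12 ms) at
activation + local APD90. Electrodes over masked-out tissue emit flat,
flagged traces. A kinematic builder (`plane_wave_spike_times`) produces
exact plane-wave activation times at a prescribed speed and angle for
conduction-velocity validation.

**What the generator does not emulate.** Specific ionic currents,
cell-to-cell heterogeneity, motion artefacts, ratiometric optics,
electrode drift and line noise, and 3-D tissue. Passing tests therefore
demonstrate correctness of the estimators under the stated forward
models, not robustness to every artefact of real recordings.

## 2. Optical preprocessing

Order of operations: sliding-window min–max normalisation (window 100
frames, centred, truncated at the ends; even windows take one extra
sample from the past, following the underlying rank-filter convention) →
mask-aware spatial Gaussian (normalised convolution, default σ = 1 px;
no printed value exists for the original kernel width, so it is exposed
in config) → per-pixel mean removal, Hanning edge taper (ramps over 10%
of the record at each end) → 4th-order Butterworth band-pass 1–30 Hz
applied forward and backward (zero net phase). `smooth_recompose`
re-synthesises a trace from its K largest in-band Fourier components
(default K = 25) — the configurable realisation of sinusoidal-basis
smoothing; it is off by default and not used by the feature extractors.

The first and last ⌈2·fs / band_low⌉ samples (2 s at 200 Hz and 1 Hz)
are flagged untrusted — filter settling plus Hilbert end effects — and
all phase/singularity analyses skip them. This is why verification
simulations run 10 s to guarantee ≥4 s of trusted frames.

## 3. AP features

Activation is the maximum-upstroke-slope instant on the raw derivative
(earliest sample on ties), refined to sub-sample precision by the
centroid of the derivative bump; the analytic trace generator reports
its truth from the same reference (mid-ramp), so estimator and oracle
use one convention. Baseline is the median over the diastolic 30% of
the preceding inter-beat interval. APD_f is the first fall below
peak − f·(peak − baseline) after the peak.

Two estimator details matter at realistic noise (white, up to 5% of AP
amplitude at 200 frames/s):

- **Peak.** The raw maximum is biased upward by noise selection. The
  estimator takes the contiguous run of samples within 2.5 estimated
  noise SD of the maximum, re-centres on that run's median, expands the
  run at a 2-SD threshold (tolerating isolated dips), and reports the
  run median — unbiased on plateaus, and within ~1.5% elsewhere.
- **Level crossing.** The crossing is refined by a linear fit of the
  falling limb over a window set in value units (up to 50–75% of the
  amplitude above the level, at most 75% of the remaining drop below,
  converted to time via a pilot slope), with a residual-based curvature
  guard that shrinks the window until locally linear and a cliff guard
  that falls back to two-point interpolation for square-pulse-like
  repolarisation.

No rate correction is applied to APDs (rate correction exists only for
field-potential durations). Calcium transients use the same machinery
with fractions (0.5, 0.9). The verification scenario draws APD90 from
80–400 ms with linear repolarisation and plateau fractions 0.2–0.45,
reproducing the triangular-to-intermediate morphologies (APD30:90 ratios
≈0.47–0.65) seen in atrial and ventricular monolayers; at these
conditions ≥95% of APD estimates land within one frame (5 ms) of the
closed-form truth, and APD is monotone in the fraction for every beat.

## 4. Phase mapping and rotors

Per-pixel instantaneous phase is the argument of the analytic signal
(Hilbert transform of the band-passed, mean-free trace), wrapped to
(−π, π]. Singularities are detected with the double-ring criterion:
wrapped successive phase differences are summed along two concentric
discrete circles (Bresenham rings, default radii 2 and 4 px, deduplicated
and traversed in angular order); a singularity requires |sum| > π on
both rings with a common sign. π is the literal criterion threshold — an
ideal singularity winds by 2π, and π tolerates discretisation.
Candidates whose rings leave the image or mask are skipped, so no
detections occur within r_outer of a border. 8-connected candidate
clusters reduce to one detection (largest inner-ring magnitude, ties to
smallest row then column; optionally the cluster centroid, which is the
sub-pixel localisation used whenever positions are compared to oracles
at 1 px tolerance).

Tracking is greedy nearest-neighbour (closest pair first) under a
10 px/frame displacement bound, equal chirality, and up to 2 bridged
frames — adequate at the ≤10 simultaneous singularities these data
produce; lifetime is (last − first frame) × frame interval.

Wavefronts are 8-connected components (≥4 px) of the activation
isophase (default φ_act = π/2; the choice shifts front geometry, never
singularity detection), linked across frames by dilated proximity
(4 px) rather than strict overlap, because a front advances farther than
its own thickness per frame. Death causes are classified as boundary,
singularity (endpoint within r_outer of a detection) or collision.

Verified end-to-end behaviour: on the default cross-field spiral the
dominant phase-based track covers all trusted frames and stays ≈3 px RMS
from the isopotential tip oracle; 10 Hz planar pacing of the same medium
yields zero tracks longer than 50 ms.

## 5. MEA features

Spikes are extrema of the first derivative within bursts exceeding an
adaptive threshold (6 × MAD of the derivative), refined by parabolic
interpolation of the derivative magnitude; detections below 25% of the
median detected amplitude are discarded as noise outliers. FPD runs
from the spike to the largest absolute deflection from the local
baseline within (spike + 50 ms, next spike − 50 ms), polarity-agnostic,
with parabolic sub-sample refinement and a 4-robust-SD noise floor; the
T-wave *peak* (not end) is the chosen endpoint, recorded in config.
FPDc = FPD / (RR in seconds)^⅓ — the Fridericia convention with the
cube-root denominator normalised to 1 s. CV comes from a least-squares
plane fit t(x, y) = t₀ + p·x + q·y over electrode positions in mm;
per-beat slowness vectors are averaged before inversion so that timing
noise cancels across beats (the verification scenario uses 400 beats
with 0.5 ms timing noise, recovering 10–80 cm/s within 5% and
rotation-invariant to 1%). Collinear geometries raise; gradients
implying speeds above 200 cm/s are flagged unresolvable. Paired drug
effects are vehicle-adjusted ratios per matched electrode,
Δ = (post/pre)/(vehicle_post/vehicle_pre), with absolute differences
alongside.

## 6. Pipeline and reproducibility

The CLI wires the stages in fixed order from one YAML file; every
output carries the SHA-256 hash of the canonical configuration, outputs
contain no timestamps, and all randomness flows from the single seed —
so a repeated run is byte-identical, which the test suite asserts at
file level. Replicate aggregation produces descriptive summaries only
(mean of per-replicate means, SD, N/n counts), explicitly labelled as
such; mixed-model inference is out of scope and belongs to downstream
statistical tooling.

**Problem sizes.** Verification uses 128 × 128 media simulated for 10 s
at 0.5 ms steps stored at 5 ms (criteria on rotors), 64 × 64 planted
vortex fields (winding-oracle equivalence, 50 fields), 200 three-beat
AP traces, and 400-beat electrode-grid scenarios — sizes at which every
check runs on one CPU in minutes while leaving the measured margins
well clear of their tolerances.

## 7. Known limitations

- The Hilbert phase needs ≈2 s of settling at the 1 Hz band edge;
  recordings shorter than ~5 s leave little trusted data.
- Greedy tracking can mis-link during close same-chirality encounters;
  global assignment would be the extension for dense multi-rotor fields.
- The exponential-repolarisation APD90 crossing is intrinsically
  shallow; at 5% white noise its single-beat estimate can err by tens of
  ms regardless of estimator, which is why the verification scenario
  uses the (morphologically appropriate) linear-repolarisation shapes.
- The wavefront extractor reports isophase geometry; it does not attempt
  conduction-velocity fields or dominant-frequency maps.
- `synth_electrograms` reads point electrodes; real electrodes integrate
  over finite area and volume-conduct from neighbouring tissue.
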