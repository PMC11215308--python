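# Methods

This note documents the models, estimators, defaults and numerical
choices behind the package, and what the synthetic data do and do not
emulate.

## The measurement being modeled

The pipeline targets simultaneous ECoG–LSCI recordings over rodent
somatosensory cortex. Laser speckle contrast imaging infers relative
perfusion from the blurring of a coherent-light speckle pattern:
moving scatterers reduce the local contrast `K = σ/μ` of the intensity
image, and the relative flow index is taken as `F = 1/K²`. The
recordings of interest are (a) a 2 frames/s, 2,400 s flow movie during
KCl-induced cortical spreading depression (CSD), (b) stimulation
blocks of 90 electrical pulses to the forepaw with the evoked cortical
potential recorded at 10 kHz, and (c) perfusion during a stimulation
block. CSD is a slowly propagating (~2–6 mm/min) depolarization wave
whose perfusion signature is triphasic: a brief hypoperfusion dip, a
large hyperemic peak, and a variable post-wave oligemia that in
pathological states fails to return to baseline.

## Synthetic data

`synthetic_data` generates every pipeline input deterministically from
a seed.

**Flow movies.** Each pixel carries
`baseline · (1 + vasomotion(t) + Σ w(t − arrival) + ε)`:

- *Vasomotion* is one spatially global band-limited Gaussian signal
  (FFT-masked white noise, 0.05–0.15 Hz, unit SD scaled by
  `vasomotion_sd`, default 2% of baseline). Real vasomotion
  decorrelates over space; a single global component is the minimal
  structure the coherence analysis needs, and inter-regional lags are
  generated explicitly by `gen_vasomotion_pair` (FFT phase-shift
  delay, exact to sub-sample precision).
- *CSD waves* propagate at constant speed from a point source
  (radially, as from a KCl application site) or as a plane wave (for
  two-ROI velocity work). The hyperemic peak arrives at
  `onset + distance/velocity`, so arrival time is affine in distance
  with slope 1/velocity. The waveform template is a −10% dip (FWHM
  5 s, leading the peak by 25 s), a +40% Gaussian hyperemic peak
  (σ = 10 s), and, for non-recovering events, a smooth transition into
  a persistent −15% oligemic plateau. The template's amplitudes are
  design choices — chosen so transients are detectable at the modeled
  noise level — since only the qualitative shape is constrained by the
  literature.
- *Measurement noise* ε is white Gaussian (default SD 3% of baseline);
  no detector physics is modeled.

Defaults: 2 frames/s × 2,400 s, 100 × 80 px at 0.05 mm/px (a
desk-scale 4 × 5 mm field; a full 1032 × 776 sensor is a config
option). Acquisition hardware often runs faster (e.g. 25 fps) than the
2 frames/s analysis rate; the generator produces the analysis rate
directly and leaves the binning/subsampling relationship open.

**SSEP epochs.** A deterministic template — positive Gaussian P1 bump
(+340 µV at 8.56 ms, σ = 1.5 ms) and negative N1 bump (−178.1 µV at
15 ms), zero before the stimulus — plus white noise (SD 30 µV) per
epoch, 90 epochs at 10 kHz. Real evoked responses have colored noise,
trial-to-trial latency jitter and amplitude drift; none of these are
modeled, so passing tests demonstrate correct averaging and component
extraction, not robustness to physiological nonstationarity.

**Stimulation traces** are a baseline / plateau / baseline step
(defaults 10 s / 40 s / 10 s, matching a stimulation block that starts
at 10 s) plus white noise. **Glucose curves** rise linearly from the
fasting level to a peak at the first post-load timepoint (default
30 min) and decay exponentially back (τ default 60 min), sampled at
0/30/60/120 min with Gaussian reading noise.

## Speckle processing

Spatial contrast uses a 7 × 7 sliding window per frame (population
σ/μ), truncated at image edges rather than padded — padding would
fabricate intensities. Windows with zero mean yield NaN (missing), and
K > ~1.2 is logged as physically implausible but not rejected. The
contrast window size and the 1/K² mapping are field conventions, not
reconstructions of any particular acquisition software; only relative
flow is meaningful (the full `K(τ_c, T)` exposure integral and
absolute calibration are out of scope).

`synthesize_speckle` draws per-pixel intensities from a Gamma
distribution with shape equal to the local flow index: averaging `N`
independent fully developed speckle patterns gives contrast `1/√N`, so
`K = 1/√F` exactly and the round trip recovers the input flow. A
single 7 × 7 window estimates K with ~10% relative error (hence ~20%
in flow); `spatial_contrast(..., time_average=True)` averages contrast
maps across frames — the standard reduction when the field is static —
bringing round-trip error to a few percent over 20 frames.

## rCBF normalization and stimulation response

`rCBF_N(Tₙ) = R(Tₙ)/R(T_b)`. The baseline window defaults to the first
60 s of the recording (before any event or stimulus) and is
configurable; its mean must be positive. The output's baseline mean is
1 by construction and the normalization is invariant to positive
rescaling of the raw trace. The stimulation response is the mean of
`rCBF_N` over the stimulation window, which must not overlap the
baseline window.

## Coherence and band lag

Welch defaults: 256-sample Hann segments (128 s at 2 frames/s), 50%
overlap, constant detrend — long enough to resolve the 0.05–0.15 Hz
band (~13 bins at 2 fps) with ~36 averaged segments over 2,400 s. The
cross spectrum uses the convention `P_AM = E[A(f)·conj(M(f))]`, so a
positive phase (and positive lag `Δt = ∅/(2πf)`) means region A leads
region M. Frequencies where either auto-spectrum vanishes yield
missing values, which are excluded from band averages rather than
zero-filled.

The band summary unwraps the in-band phase along frequency before
converting to per-bin lags — a delay of 4 s exceeds half a period at
0.15 Hz, so raw phases would alias. The single reported lag is the
coherence-weighted average of per-bin lags (how a band should be
collapsed to one number is an open choice; coherence weighting lets
the well-determined bins dominate), reported alongside the band-mean
coherence and flagged valid only when that mean exceeds 0.5. A
per-bin threshold mode is available. Note the phase-to-time conversion
requires the 2π factor when phase is in radians; a conversion without
it (i.e. reading phase in cycles) does not produce seconds and fails
the known-delay recovery oracle.

## CSD detection and velocity

Detection operates on the normalized trace: moving-average smoothing
(5 s), `scipy.signal.find_peaks` with a prominence threshold (default
0.2 rCBF_N) interpreted relative to the trace's baseline-window level
(making detection exactly invariant to positive rescaling), and a
120 s refractory period. Peak times are refined by a quadratic fit
over ±15 s around the discrete maximum: at 2 frames/s the raw sample
grid limits delay resolution to 0.5 s and noise jitters the raw argmax
by several seconds on a σ = 10 s peak, while the fit localizes the
vertex to well under a second at 3% noise. The hyperemic peak — not
the preceding dip — defines event timing.

Recovery is judged against the baseline-window level, not the global
median (a long non-recovering plateau would drag the median to the
plateau itself): an event is `recovered` when the trace median over
[peak + 60 s, peak + 120 s] is within ±5% of baseline. Events too
close to the end of the recording are judged from the trailing 60 s.

Velocity pairs events across the two ROIs in order of occurrence, up
to the shorter list (with a warning on count mismatch), rejecting
pairs whose delay implies propagation slower than 1 mm/min as spurious.
Both the first-pair velocity and the per-pair mean are reported, since
a per-animal figure could be either. The number of detected events is
reported as a single count (event/occurrence labels map to the same
quantity).

## SSEP analysis

Epochs are cut with a (pre, post) window around each stimulus and
baseline-corrected by the pre-stimulus mean; overlapping windows are
rejected with a diagnostic. The stimulation pulse rate is an input
(default 3 Hz — at 90 pulses per 30 s block; some protocols quote
5 Hz, so the rate is never hard-coded). The analysis window defaults
to 50 ms post-stimulus: a sub-millisecond averaging window cannot
contain a component at ~8.6 ms latency.

P1 is the first post-stimulus local maximum whose prominence exceeds
20% of the window's range. The guard exists because a literal "first
local maximum" is ill-posed on noisy averages: residual noise
(~3 µV after 90 epochs) produces ripples in the pre-response baseline
that would otherwise be reported as P1 at near-zero latency.
Localization runs on a 0.7 ms moving-average copy with quadratic
refinement over ±1 ms snapped back to the sample grid (sub-sample
interpolation off by default); amplitudes are read from the unsmoothed
waveform at the chosen samples, so smoothing never attenuates the
reported amplitude. N1 is the global minimum after P1 in the window.
Reported quantities: peak-to-peak amplitude `P1 − N1` (both components
are defined, and a single per-group amplitude is conventionally
peak-to-peak) and latency = time to P1. Units are carried as µV but
all arithmetic is unit-agnostic.

## Metabolic statistics

Glucose AUC is the trapezoidal integral over the sampled times
(mg·min/dL), by default without baseline subtraction; the incremental
(t = 0 subtracted) variant is also emitted since either convention
appears in practice. The diabetic classification is `level ≥ 288
mg/dL`, inclusive. Group summaries give n/mean/SD/SEM and, for exactly
two groups of n ≥ 2, a two-sided Welch unpaired t test; Sidak and
Tukey family corrections are thin pass-throughs to standard routines.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale problems: full-length
2,400 s traces (4,800 samples) wherever the protocol's duration
matters, movies of tens of pixels per side and a few hundred frames
for end-to-end wave recovery, 90 × 600-sample epoch sets, and 100-seed
Monte-Carlo loops for detection-rate checks. Every stochastic stage
takes an explicit seed (`numpy.random.default_rng`); fixed seed means
bit-identical output.

## Known limitations

- Vasomotion has no spatial decorrelation structure; coherence between
  ROIs of one synthetic movie is near 1 by construction.
- The CSD waveform is a fixed template; real waves change shape as
  they propagate, which would bias peak-delay velocity estimates in
  ways the synthetic tests cannot reveal.
- The speckle model is per-pixel independent Gamma statistics: no
  finite speckle grain size, detector noise, or exposure-time physics.
- Epoch extraction assumes artifact-free recordings; there is no
  artifact rejection beyond baseline correction, and hardware filter
  characteristics (e.g. a 0.5–7,500 Hz bandpass) are metadata only.
- Event pairing across ROIs is by order of occurrence; it will
  mis-pair if a wave is detected in only one region between shared
  events.
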