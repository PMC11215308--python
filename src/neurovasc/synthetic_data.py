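"""Synthetic generators for every input the pipeline consumes.

The study design being emulated: a craniotomy window over rat
somatosensory cortex imaged with laser speckle contrast at 2 frames/s
for 2,400 s while KCl induces cortical spreading depression (CSD) —
slow (a few mm/min) waves of depolarization with a triphasic perfusion
signature (brief hypoperfusion dip, large hyperemic peak, optional
post-wave oligemia); spontaneous vasomotion occupies the 0.05–0.15 Hz
band.  Separately, forepaw electrical stimulation yields 90
stimulation-locked SSEP epochs (positive P1 peak then N1 trough) and a
perfusion plateau during the stimulation block, and intraperitoneal
glucose/insulin tolerance tests yield four-point glucose curves.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import EpochSet, FlowMovie, GlucoseSeries, NormalizedTrace, ROITrace

__all__ = [
    "CSDWaveSpec",
    "SimConfig",
    "SSEPSimConfig",
    "GlucoseSimConfig",
    "csd_waveform",
    "band_limited_noise",
    "delay_signal",
    "gen_flow_movie",
    "gen_csd_trace",
    "gen_vasomotion_pair",
    "gen_ssep_epochs",
    "ssep_template",
    "gen_stim_trace",
    "gen_glucose_table",
]


# --------------------------------------------------------------------------
# wave and noise primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CSDWaveSpec:
    """One propagating CSD transient.

    The perfusion waveform, relative to baseline (fraction units), is a
    triphasic template: a brief hypoperfusion dip preceding the front, a
    hyperemic Gaussian peak, and — when ``recovers_to_baseline`` is
    False — a persistent oligemic plateau below baseline to the end of
    the recording.  The wave front propagates from ``origin_xy_mm``
    either radially (point source, the KCl application site) or as a
    plane wave along ``direction`` (used for two-ROI velocity tests).
    """

    origin_xy_mm: tuple[float, float] = (0.0, 0.0)
    onset_s: float = 300.0
    velocity_mm_per_min: float = 4.0
    peak_frac: float = 0.40
    peak_sigma_s: float = 10.0
    dip_frac: float = 0.10
    dip_duration_s: float = 5.0
    dip_lead_s: float = 25.0
    oligemia_frac: float = 0.15
    recovers_to_baseline: bool = True
    kind: str = "radial"  # "radial" | "planar"
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.velocity_mm_per_min <= 0:
            raise ValueError("CSD wave velocity must be positive")
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if self.kind not in ("radial", "planar"):
            raise ValueError(f"unknown wave kind {self.kind!r}")
        if self.peak_sigma_s <= 0 or self.dip_duration_s <= 0:
            raise ValueError("waveform widths must be positive")


def csd_waveform(t_rel_s: np.ndarray, spec: CSDWaveSpec) -> np.ndarray:
    """Triphasic CSD perfusion waveform as a fraction of baseline.

    ``t_rel_s`` is time relative to the hyperemic peak at this location
    (the peak sits at t = 0 exactly, so peak arrival time is an affine
    function of distance from the origin with slope 1/velocity).
    """
    t = np.asarray(t_rel_s, dtype=float)
    sigma_dip = spec.dip_duration_s / 2.355  # FWHM -> sigma
    w = spec.peak_frac * np.exp(-0.5 * (t / spec.peak_sigma_s) ** 2)
    w -= spec.dip_frac * np.exp(-0.5 * ((t + spec.dip_lead_s) / sigma_dip) ** 2)
    if not spec.recovers_to_baseline:
        # smooth transition into a persistent oligemic plateau
        onset = 3.0 * spec.peak_sigma_s
        w -= spec.oligemia_frac / (1.0 + np.exp(-(t - onset) / 10.0))
    return w


def band_limited_noise(
    n: int, fs_hz: float, band_hz: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD Gaussian noise with spectral support restricted to a band.

    White Gaussian noise is filtered by zeroing all rFFT coefficients
    outside ``band_hz`` and rescaled to unit standard deviation.
    """
    lo, hi = band_hz
    if not (0 < lo < hi < fs_hz / 2):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    if sd == 0:  # pragma: no cover - requires degenerate n
        raise ValueError("band contains no FFT bins at this length")
    return out / sd


def delay_signal(x: np.ndarray, delay_s: float, fs_hz: float) -> np.ndarray:
    """Circularly delay a signal by an arbitrary (sub-sample) amount."""
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs_hz)
    return np.fft.irfft(spec * np.exp(-2j * np.pi * freqs * delay_s), n=x.size)


# --------------------------------------------------------------------------
# flow-movie generator
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of a synthetic flow-index movie.

    Defaults follow the acquisition protocol being emulated: 2 frames/s
    for 2,400 s, vasomotion in 0.05–0.15 Hz.  The default desk-scale
    grid is 100 x 80 px at 0.05 mm/px (a 4 x 5 mm field); a full-frame
    1032 x 776 sensor is a configuration choice, not the default.
    """

    seed: int = 0
    frame_rate_hz: float = 2.0
    duration_s: float = 2400.0
    grid_shape: tuple[int, int] = (100, 80)  # (rows, cols)
    pixel_size_mm: float = 0.05
    baseline_flow: float = 100.0
    vasomotion_band_hz: tuple[float, float] = (0.05, 0.15)
    vasomotion_sd: float = 0.02  # fraction of baseline
    csd_events: Sequence[CSDWaveSpec] = field(default_factory=tuple)
    noise_sd: float = 0.03  # fraction of baseline

    def __post_init__(self) -> None:
        lo, hi = self.vasomotion_band_hz
        if not (0 < lo < hi < self.frame_rate_hz / 2):
            raise ValueError("vasomotion band must satisfy 0 < low < high < Nyquist")
        n_frames = self.duration_s * self.frame_rate_hz
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("duration_s * frame_rate_hz must be an integer frame count")
        if self.baseline_flow <= 0:
            raise ValueError("baseline_flow must be positive")
        if self.vasomotion_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be at least 1x1")
        for ev in self.csd_events:
            if ev.onset_s >= self.duration_s:
                raise ValueError("CSD onset must fall within the recording")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def _arrival_map(spec: CSDWaveSpec, config: SimConfig) -> np.ndarray:
    """Hyperemic-peak arrival time (s) at every pixel."""
    rows, cols = config.grid_shape
    y = (np.arange(rows)[:, None] + 0.5) * config.pixel_size_mm
    x = (np.arange(cols)[None, :] + 0.5) * config.pixel_size_mm
    ox, oy = spec.origin_xy_mm
    v_mm_s = spec.velocity_mm_per_min / 60.0
    if spec.kind == "radial":
        dist = np.sqrt((x - ox) ** 2 + (y - oy) ** 2)
    else:
        dx, dy = spec.direction
        norm = math.hypot(dx, dy)
        if norm == 0:
            raise ValueError("planar wave direction must be non-zero")
        dist = ((x - ox) * dx + (y - oy) * dy) / norm
        dist = np.maximum(dist, 0.0)  # front starts at the origin plane
    return spec.onset_s + np.broadcast_to(dist, (rows, cols)) / v_mm_s


def gen_flow_movie(config: SimConfig) -> FlowMovie:
    """Generate a flow-index movie with vasomotion, CSD waves and noise.

    Each pixel's value at frame time t is::

        baseline * (1 + vasomotion(t) + sum_waves w(t - arrival(px)) + eps)

    where ``arrival(px) = onset + distance(origin, px) / velocity`` and
    ``eps`` is white Gaussian measurement noise.  Vasomotion is a single
    band-limited signal shared by all pixels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    rows, cols = config.grid_shape
    t = np.arange(n) / config.frame_rate_hz

    rel = np.zeros((n, rows, cols))
    if config.vasomotion_sd > 0:
        vas = band_limited_noise(n, config.frame_rate_hz, config.vasomotion_band_hz, rng)
        rel += (config.vasomotion_sd * vas)[:, None, None]
    for spec in config.csd_events:
        arrival = _arrival_map(spec, config)
        rel += csd_waveform(t[:, None, None] - arrival[None, :, :], spec)
    if config.noise_sd > 0:
        rel += config.noise_sd * rng.standard_normal((n, rows, cols))

    frames = config.baseline_flow * (1.0 + rel)
    return FlowMovie(frames=frames, frame_rate_hz=config.frame_rate_hz,
                     pixel_size_mm=config.pixel_size_mm)


# --------------------------------------------------------------------------
# trace-level generators
# --------------------------------------------------------------------------

def gen_csd_trace(
    peak_times_s: Sequence[float],
    *,
    duration_s: float = 2400.0,
    sampling_rate_hz: float = 2.0,
    noise_sd: float = 0.03,
    seed: int = 0,
    wave: Optional[CSDWaveSpec] = None,
    recovers: Optional[Sequence[bool]] = None,
    baseline_window_s: tuple[float, float] = (0.0, 60.0),
) -> NormalizedTrace:
    """Normalized rCBF trace containing triphasic CSD transients.

    Each entry of ``peak_times_s`` places one transient with its
    hyperemic peak at that time.  ``recovers`` optionally overrides the
    template's return-to-baseline flag per event (a False entry leaves a
    persistent oligemic plateau).  Noise is white Gaussian with SD
    ``noise_sd`` in rCBF_N units.
    """
    base = wave if wave is not None else CSDWaveSpec()
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    rng = np.random.default_rng(seed)
    values = np.ones(n)
    for k, pt in enumerate(peak_times_s):
        if not (0 <= pt < duration_s):
            raise ValueError("peak times must fall within the recording")
        spec = base
        if recovers is not None:
            spec = CSDWaveSpec(**{**base.__dict__, "recovers_to_baseline": bool(recovers[k])})
        values += csd_waveform(t - pt, spec)
    if noise_sd > 0:
        values += noise_sd * rng.standard_normal(n)
    return NormalizedTrace(
        rcbf_n=values,
        sampling_rate_hz=sampling_rate_hz,
        baseline_window=baseline_window_s,
        baseline_value=1.0,
    )


def gen_vasomotion_pair(
    *,
    duration_s: float = 2400.0,
    sampling_rate_hz: float = 2.0,
    delay_s: float = 2.0,
    band_hz: tuple[float, float] = (0.05, 0.15),
    baseline: float = 100.0,
    vasomotion_sd: float = 0.05,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[ROITrace, ROITrace]:
    """Two ROI traces sharing one vasomotion signal with a known lag.

    Trace A carries the common band-limited vasomotion component; trace
    M carries the same component delayed by ``delay_s`` (so A leads M).
    Each trace receives independent white measurement noise.  This is
    the ground-truth generator for the coherence/phase/lag analysis.
    """
    n = int(round(duration_s * sampling_rate_hz))
    rng = np.random.default_rng(seed)
    common = band_limited_noise(n, sampling_rate_hz, band_hz, rng)
    lagged = delay_signal(common, delay_s, sampling_rate_hz)
    noise_a = rng.standard_normal(n)
    noise_m = rng.standard_normal(n)
    a = baseline * (1 + vasomotion_sd * common + noise_sd * noise_a)
    m = baseline * (1 + vasomotion_sd * lagged + noise_sd * noise_m)
    return (
        ROITrace(values=a, sampling_rate_hz=sampling_rate_hz),
        ROITrace(values=m, sampling_rate_hz=sampling_rate_hz),
    )


# --------------------------------------------------------------------------
# SSEP generator
# --------------------------------------------------------------------------

@dataclass
class SSEPSimConfig:
    """Configuration for simulated stimulation-locked SSEP epochs.

    The deterministic template has a positive Gaussian P1 bump and a
    negative N1 bump; each of the ``n_epochs`` epochs is template plus
    white Gaussian noise.  Defaults place P1 at +340 uV / 8.56 ms and N1
    at -178.1 uV / 15 ms, the control-group response being emulated.
    """

    seed: int = 0
    sampling_rate_hz: float = 10_000.0
    n_epochs: int = 90
    pre_s: float = 0.010
    epoch_window_s: float = 0.050  # post-stimulus extent
    p1_amp_uV: float = 340.0
    p1_latency_ms: float = 8.56
    n1_amp_uV: float = 178.1  # trough depth (positive number)
    n1_latency_ms: float = 15.0
    peak_width_ms: float = 1.5  # Gaussian sigma
    noise_sd_uV: float = 30.0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.n1_latency_ms <= self.p1_latency_ms:
            raise ValueError("N1 latency must follow P1 latency")
        if self.epoch_window_s * 1000.0 <= self.n1_latency_ms:
            raise ValueError("epoch window is shorter than the N1 latency")
        if self.pre_s < 0 or self.noise_sd_uV < 0:
            raise ValueError("pre_s and noise_sd_uV must be non-negative")
        if self.peak_width_ms <= 0:
            raise ValueError("peak_width_ms must be positive")


def ssep_template(config: SSEPSimConfig) -> np.ndarray:
    """Noise-free SSEP template over the epoch window (uV)."""
    fs = config.sampling_rate_hz
    n_pre = int(round(config.pre_s * fs))
    n_post = int(round(config.epoch_window_s * fs))
    t_ms = (np.arange(n_pre + n_post) - n_pre) / fs * 1000.0
    sig = config.peak_width_ms
    tpl = config.p1_amp_uV * np.exp(-0.5 * ((t_ms - config.p1_latency_ms) / sig) ** 2)
    tpl -= config.n1_amp_uV * np.exp(-0.5 * ((t_ms - config.n1_latency_ms) / sig) ** 2)
    tpl[t_ms < 0] = 0.0  # no response before the stimulus
    return tpl


def gen_ssep_epochs(config: SSEPSimConfig) -> EpochSet:
    """Simulate ``n_epochs`` stimulation-locked epochs (template + noise)."""
    rng = np.random.default_rng(config.seed)
    tpl = ssep_template(config)
    epochs = np.tile(tpl, (config.n_epochs, 1))
    if config.noise_sd_uV > 0:
        epochs = epochs + config.noise_sd_uV * rng.standard_normal(epochs.shape)
    n_pre = int(round(config.pre_s * config.sampling_rate_hz))
    return EpochSet(
        epochs=epochs,
        sampling_rate_hz=config.sampling_rate_hz,
        stim_onset_index=n_pre,
        window_s=(-config.pre_s, config.epoch_window_s),
    )


# --------------------------------------------------------------------------
# stimulation-evoked perfusion trace
# --------------------------------------------------------------------------

def gen_stim_trace(
    baseline: float,
    plateau_ratio: float,
    pre_s: float = 10.0,
    stim_s: float = 40.0,
    post_s: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate_hz: float = 2.0,
) -> ROITrace:
    """ROI flow trace with a stimulation-evoked perfusion plateau.

    The trace sits at ``baseline`` for ``pre_s`` seconds, steps to
    ``baseline * plateau_ratio`` for the ``stim_s`` stimulation block,
    and returns to baseline for ``post_s`` seconds; white Gaussian noise
    of SD ``noise_sd`` (flow units) is added throughout.
    """
    if plateau_ratio <= 0:
        raise ValueError("plateau_ratio must be positive")
    if min(pre_s, stim_s, post_s) <= 0:
        raise ValueError("all segment durations must be positive")
    rng = np.random.default_rng(seed)
    n = int(round((pre_s + stim_s + post_s) * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    values = np.full(n, float(baseline))
    stim_mask = (t >= pre_s) & (t < pre_s + stim_s)
    values[stim_mask] = baseline * plateau_ratio
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(n)
    return ROITrace(values=values, sampling_rate_hz=sampling_rate_hz)


# --------------------------------------------------------------------------
# glucose tolerance curves
# --------------------------------------------------------------------------

@dataclass
class GlucoseSimConfig:
    """Configuration of a simulated glucose tolerance curve.

    The curve starts at ``fasting_level`` at t = 0, rises to
    ``peak_level`` at the first post-load timepoint, then decays
    exponentially back toward fasting with time constant
    ``decay_tau_min``.  Gaussian measurement noise is added per reading.
    """

    seed: int = 0
    timepoints_min: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0)
    fasting_level: float = 109.5
    peak_level: float = 250.0
    decay_tau_min: float = 60.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_min, dtype=float)
        if tp.size < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing, length >= 2")
        if self.fasting_level < 0 or self.peak_level < 0:
            raise ValueError("glucose levels must be non-negative")
        if self.decay_tau_min <= 0:
            raise ValueError("decay_tau_min must be positive")


def gen_glucose_table(
    config: GlucoseSimConfig, subject_id: str = "", condition: str = ""
) -> GlucoseSeries:
    """Simulate a glucose tolerance curve at the configured timepoints."""
    rng = np.random.default_rng(config.seed)
    tp = np.asarray(config.timepoints_min, dtype=float)
    t_peak = tp[1] if tp[0] == 0 else tp[0]
    values = np.empty_like(tp)
    for i, t in enumerate(tp):
        if t < t_peak:
            # linear rise from fasting to the peak
            frac = t / t_peak if t_peak > 0 else 0.0
            values[i] = config.fasting_level + frac * (config.peak_level - config.fasting_level)
        else:
            decay = np.exp(-(t - t_peak) / config.decay_tau_min)
            values[i] = config.fasting_level + (config.peak_level - config.fasting_level) * decay
    if config.noise_sd > 0:
        values = values + config.noise_sd * rng.standard_normal(values.shape)
    values = np.maximum(values, 0.0)
    return GlucoseSeries(times_min=tp, values_mg_dl=values,
                         subject_id=subject_id, condition=condition)
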