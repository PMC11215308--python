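"""ROI traces, rCBF normalization, stimulation response, and coherence/lag.

Normalization: ``rCBF_N(Tn) = R(Tn) / R(Tb)`` where ``R(Tb)`` is the
mean resting flow over a pre-event baseline window, so the normalized
trace has baseline mean 1 and is invariant to rescaling the raw trace.

Inter-regional timing of slow vasomotion (0.05–0.15 Hz) is quantified
with the magnitude-squared coherence

    Coh2_AM(f) = |P_AM(f)|**2 / (P_AA(f) * P_MM(f)),

estimated by Welch's overlapped averaged periodogram, with the cross
phase  phi(f) = atan2(Im P_AM, Re P_AM)  converted to a time lag
``dt(f) = phi(f) / (2 pi f)``.  Sign convention: positive phase (and
positive lag) means trace A leads trace M.  The band lag is only
reported as valid when the band-mean coherence exceeds a threshold
(default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import FlowMovie, NormalizedTrace, ROISpec, ROITrace

__all__ = [
    "WelchParams",
    "CoherenceSpectrum",
    "LagEstimate",
    "StimResponse",
    "extract_roi_trace",
    "normalize_rcbf",
    "stim_response",
    "compute_coherence",
    "band_phase_lag",
]


def _window_slice(start_s: float, end_s: float, fs: float, n: int, what: str) -> slice:
    if not (0 <= start_s < end_s):
        raise ValueError(f"{what} must satisfy 0 <= start < end")
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    if i0 >= n or i1 > n:
        raise ValueError(f"{what} ({start_s}, {end_s}) s extends past the trace")
    if i1 <= i0:
        raise ValueError(f"{what} contains no samples at {fs} Hz")
    return slice(i0, i1)


# --------------------------------------------------------------------------
# ROI extraction and normalization
# --------------------------------------------------------------------------

def roi_mask(movie: FlowMovie, roi: ROISpec) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the circle."""
    _, rows, cols = movie.frames.shape
    px = movie.pixel_size_mm
    x = (np.arange(cols)[None, :] + 0.5) * px
    y = (np.arange(rows)[:, None] + 0.5) * px
    cx, cy = roi.center_xy_mm
    return (x - cx) ** 2 + (y - cy) ** 2 <= roi.radius_mm**2


def extract_roi_trace(movie: FlowMovie, roi: ROISpec) -> ROITrace:
    """Mean flow over the in-circle pixels, one value per frame.

    Pixel inclusion is center-in-circle, with the mm -> px conversion
    given by the movie's ``pixel_size_mm``.  An ROI covering zero pixel
    centers is an error.
    """
    mask = roi_mask(movie, roi)
    if not mask.any():
        raise ValueError(
            f"ROI at {roi.center_xy_mm} mm, radius {roi.radius_mm} mm covers no pixel centers"
        )
    values = movie.frames[:, mask].mean(axis=1)
    return ROITrace(values=values, sampling_rate_hz=movie.frame_rate_hz, roi=roi)


def normalize_rcbf(
    trace: ROITrace, baseline_window: tuple[float, float] = (0.0, 60.0)
) -> NormalizedTrace:
    """Baseline-normalize an ROI trace to rCBF_N units.

    ``R(Tb)`` is the mean over ``baseline_window`` (seconds); a
    non-positive baseline is non-physical and raises.
    """
    sl = _window_slice(*baseline_window, trace.sampling_rate_hz, trace.values.size,
                       "baseline window")
    r_tb = float(np.mean(trace.values[sl]))
    if r_tb <= 0:
        raise ValueError(f"non-physical baseline mean {r_tb}")
    return NormalizedTrace(
        rcbf_n=trace.values / r_tb,
        sampling_rate_hz=trace.sampling_rate_hz,
        baseline_window=baseline_window,
        baseline_value=r_tb,
        roi=trace.roi,
    )


@dataclass
class StimResponse:
    """Mean normalized perfusion during a stimulation window."""

    pre_window: tuple[float, float]
    stim_window: tuple[float, float]
    normalized_stim_mean: float


def stim_response(
    ntrace: NormalizedTrace, stim_window: tuple[float, float]
) -> StimResponse:
    """Mean rCBF_N over the stimulation window (pre window = baseline)."""
    pre = ntrace.baseline_window
    if not (pre[1] <= stim_window[0] or stim_window[1] <= pre[0]):
        raise ValueError("stimulation window must not overlap the baseline window")
    sl = _window_slice(*stim_window, ntrace.sampling_rate_hz, ntrace.rcbf_n.size,
                       "stimulation window")
    return StimResponse(
        pre_window=pre,
        stim_window=stim_window,
        normalized_stim_mean=float(np.mean(ntrace.rcbf_n[sl])),
    )


# --------------------------------------------------------------------------
# coherence and lag
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchParams:
    """Welch periodogram settings (defaults: 256-sample Hann segments,
    50% overlap — 128 s segments at 2 frames/s)."""

    nperseg: int = 256
    noverlap: Optional[int] = None  # None -> nperseg // 2
    window: str = "hann"
    detrend: str = "constant"

    @property
    def step(self) -> int:
        return self.nperseg - (self.noverlap if self.noverlap is not None else self.nperseg // 2)


@dataclass
class CoherenceSpectrum:
    freqs_hz: np.ndarray
    coherence: np.ndarray  # Coh2 in [0, 1]; NaN where undefined
    cross_phase_rad: np.ndarray  # phase of P_AM; positive => A leads
    psd_a: np.ndarray
    psd_m: np.ndarray
    csd_am: np.ndarray  # complex cross-spectrum P_AM = E[A(f) conj(M(f))]
    welch_params: WelchParams


def compute_coherence(
    trace_a: ROITrace,
    trace_m: ROITrace,
    welch: WelchParams = WelchParams(),
) -> CoherenceSpectrum:
    """Magnitude-squared coherence and cross phase of two ROI traces.

    ``Coh2 = |P_AM|**2 / (P_AA * P_MM)`` with all three densities from
    Welch's method.  Frequencies where either auto-spectrum is zero get
    NaN coherence (missing value, never zero-filled).  The cross
    spectrum uses the convention ``P_AM(f) = E[A(f) * conj(M(f))]`` so
    that a positive phase means A leads M.
    """
    a, m = trace_a.values, trace_m.values
    if a.size != m.size:
        raise ValueError("traces must have equal length")
    if trace_a.sampling_rate_hz != trace_m.sampling_rate_hz:
        raise ValueError("traces must share a sampling rate")
    fs = trace_a.sampling_rate_hz
    noverlap = welch.noverlap if welch.noverlap is not None else welch.nperseg // 2
    if a.size < welch.nperseg + welch.step:
        raise ValueError("traces must span at least 2 Welch segments")

    kw = dict(fs=fs, window=welch.window, nperseg=welch.nperseg,
              noverlap=noverlap, detrend=welch.detrend)
    freqs, p_aa = sps.welch(a, **kw)
    _, p_mm = sps.welch(m, **kw)
    # scipy's csd(x, y) estimates E[conj(X) Y]; conjugate to get E[A conj(M)]
    _, p_am = sps.csd(a, m, **kw)
    p_am = np.conj(p_am)

    denom = p_aa * p_mm
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(p_am) ** 2 / denom
    coh[denom == 0] = np.nan
    coh = np.clip(coh, 0.0, 1.0)
    phase = np.angle(p_am)
    phase[denom == 0] = np.nan
    return CoherenceSpectrum(
        freqs_hz=freqs, coherence=coh, cross_phase_rad=phase,
        psd_a=p_aa, psd_m=p_mm, csd_am=p_am, welch_params=welch,
    )


@dataclass
class LagEstimate:
    """Band-summarized phase and time lag between two regions."""

    band_hz: tuple[float, float]
    mean_band_coherence: float
    phase_rad: float
    lag_s: float
    valid: bool
    n_bins: int


def band_phase_lag(
    spec: CoherenceSpectrum,
    band_hz: tuple[float, float] = (0.05, 0.15),
    coh_threshold: float = 0.5,
    per_bin_threshold: bool = False,
) -> LagEstimate:
    """Summarize phase and time lag over a frequency band.

    Per-bin lag is ``dt(f) = phi(f) / (2 pi f)`` with the in-band phase
    unwrapped along frequency (delays beyond half a period at the top of
    the band would otherwise alias).  The band lag and phase are
    coherence-weighted averages over in-band bins; bins with undefined
    coherence are excluded.  ``valid`` requires the band-mean coherence
    (or, with ``per_bin_threshold``, every retained bin) to exceed
    ``coh_threshold``; when invalid the lag value is still carried, but
    flagged as not interpretable.
    """
    lo, hi = band_hz
    in_band = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not in_band.any():
        raise ValueError(f"no frequency bins inside the band {band_hz} Hz")
    ok = in_band & np.isfinite(spec.coherence) & np.isfinite(spec.cross_phase_rad)
    if not ok.any():
        raise ValueError("all in-band bins have undefined coherence")

    freqs = spec.freqs_hz[ok]
    coh = spec.coherence[ok]
    phase = np.unwrap(spec.cross_phase_rad[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        dt = phase / (2.0 * np.pi * freqs)
    wsum = coh.sum()
    if wsum == 0:
        raise ValueError("zero total coherence weight in band")
    lag = float(np.sum(coh * dt) / wsum)
    mean_phase = float(np.sum(coh * phase) / wsum)
    mean_coh = float(coh.mean())
    if per_bin_threshold:
        valid = bool(np.all(coh > coh_threshold))
    else:
        valid = mean_coh > coh_threshold
    if not valid:
        warnings.warn(
            f"band-mean coherence {mean_coh:.3f} below threshold {coh_threshold}; "
            "lag estimate flagged invalid",
            stacklevel=2,
        )
    return LagEstimate(
        band_hz=band_hz, mean_band_coherence=mean_coh, phase_rad=mean_phase,
        lag_s=lag, valid=valid, n_bins=int(ok.sum()),
    )
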