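"""Somatosensory evoked potential (SSEP) epoching and component analysis.

A stimulation block delivers a train of identical pulses; the cortical
response to each pulse is cut out as an epoch, baseline-corrected by its
pre-stimulus mean, and the epochs are averaged pointwise (noise shrinks
as 1/sqrt(n)).  The averaged waveform is decomposed into the two
standard components: P1, the first maximum after the stimulus, and N1,
the minimum that follows it.  Reported quantities are the peak-to-peak
amplitude ``P1 - N1`` and the latency (time to P1 in ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import EpochSet

__all__ = [
    "SSEPResult",
    "extract_epochs",
    "average_epochs",
    "extract_components",
]


@dataclass
class SSEPResult:
    p1_latency_ms: float
    p1_amp_uV: float
    n1_latency_ms: float
    n1_amp_uV: float
    amplitude_pp_uV: float  # p1_amp - n1_amp
    latency_ms: float  # reported latency = time to P1

    def __post_init__(self) -> None:
        if self.amplitude_pp_uV < 0:
            raise ValueError("peak-to-peak amplitude cannot be negative")
        if self.p1_latency_ms <= 0 or self.n1_latency_ms <= 0:
            raise ValueError("latencies must be positive")


def extract_epochs(
    signal_uV: np.ndarray,
    stim_times_s: Sequence[float],
    window_s: tuple[float, float],
    sampling_rate_hz: float,
) -> EpochSet:
    """Cut stimulation-locked epochs out of a continuous trace.

    ``window_s = (pre_s, post_s)`` extends each epoch from ``pre_s``
    before to ``post_s`` after the stimulus.  Epochs are baseline
    corrected by subtracting each epoch's pre-stimulus mean (when
    ``pre_s`` is 0 the epoch's first sample is used as the baseline).
    Stimulus times must be sorted, every window must lie inside the
    signal, and consecutive windows must not overlap.
    """
    x = np.asarray(signal_uV, dtype=float).ravel()
    stim = np.asarray(stim_times_s, dtype=float)
    if stim.size < 1:
        raise ValueError("need at least one stimulus time")
    if np.any(np.diff(stim) < 0):
        raise ValueError("stimulus times must be sorted")
    pre_s, post_s = window_s
    if pre_s < 0 or post_s <= 0:
        raise ValueError("window must satisfy pre_s >= 0 and post_s > 0")
    if stim.size > 1 and np.min(np.diff(stim)) < pre_s + post_s:
        raise ValueError(
            f"epoch windows overlap: minimum stimulus spacing "
            f"{np.min(np.diff(stim)):.4f} s < window {pre_s + post_s:.4f} s"
        )
    fs = sampling_rate_hz
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    rows = []
    for t in stim:
        onset = int(round(t * fs))
        i0, i1 = onset - n_pre, onset + n_post
        if i0 < 0 or i1 > x.size:
            raise ValueError(f"stimulus at {t} s has a window outside the signal")
        ep = x[i0:i1].copy()
        baseline = ep[:n_pre].mean() if n_pre > 0 else ep[0]
        rows.append(ep - baseline)
    return EpochSet(
        epochs=np.vstack(rows),
        sampling_rate_hz=fs,
        stim_onset_index=n_pre,
        window_s=(-pre_s, post_s),
    )


def average_epochs(epochs: EpochSet) -> np.ndarray:
    """Pointwise mean across epochs (uV per sample)."""
    return epochs.epochs.mean(axis=0)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with truncated edges."""
    if width <= 1:
        return x
    k = np.ones(width)
    return np.convolve(x, k, "same") / np.convolve(np.ones_like(x), k, "same")


def extract_components(
    avg: np.ndarray,
    sampling_rate_hz: float,
    stim_onset_index: int = 0,
    search_window_ms: tuple[float, float] = (0.0, 50.0),
    min_prominence_frac: float = 0.2,
    smooth_ms: float = 0.7,
    refine_ms: float = 1.0,
) -> SSEPResult:
    """P1/N1 decomposition of an averaged SSEP waveform.

    P1 is the first local maximum after stimulus onset inside the search
    window with prominence at least ``min_prominence_frac`` times the
    window's peak-to-peak range (the guard keeps residual-noise ripples
    in the pre-response baseline from being reported as P1).  Peak
    localization runs on a lightly smoothed copy of the waveform
    (moving average of ``smooth_ms``) and the P1 index is refined by a
    quadratic fit over +/- ``refine_ms`` snapped back to the sample grid
    — sub-sample interpolation stays off, latencies land on samples.
    Amplitudes are read from the unsmoothed waveform.  N1 is the global
    minimum after P1 inside the window.  Raises when no qualifying
    post-stimulus maximum exists (e.g. a monotone decay).
    """
    avg = np.asarray(avg, dtype=float).ravel()
    fs = sampling_rate_hz
    lo_ms, hi_ms = search_window_ms
    if lo_ms < 0 or hi_ms <= lo_ms:
        raise ValueError("search window must satisfy 0 <= start < end")
    i0 = stim_onset_index + int(round(lo_ms / 1000.0 * fs))
    i1 = stim_onset_index + int(round(hi_ms / 1000.0 * fs))
    if i0 >= avg.size:
        raise ValueError("search window lies outside the waveform")
    i1 = min(i1, avg.size)
    seg = avg[i0:i1]
    if seg.size < 3:
        raise ValueError("search window too short for component analysis")

    width = max(1, int(round(smooth_ms / 1000.0 * fs)) | 1)
    sm = _smooth(seg, width)
    rng_pp = float(sm.max() - sm.min())
    peaks, _ = find_peaks(sm, prominence=min_prominence_frac * rng_pp if rng_pp > 0 else None)
    if peaks.size == 0:
        raise ValueError(
            "no post-stimulus local maximum found in the search window "
            f"({lo_ms}-{hi_ms} ms); cannot define P1"
        )
    p1_idx = int(peaks[0])
    half = int(round(refine_ms / 1000.0 * fs))
    lo = max(0, p1_idx - half)
    hi = min(sm.size, p1_idx + half + 1)
    if hi - lo >= 5:
        t = np.arange(lo, hi, dtype=float)
        a, b, _ = np.polyfit(t, sm[lo:hi], 2)
        if a < 0:
            vertex = -b / (2.0 * a)
            if lo <= vertex <= hi - 1:
                p1_idx = int(round(vertex))
    p1_amp = float(seg[p1_idx])
    p1_latency_ms = (i0 + p1_idx - stim_onset_index) / fs * 1000.0

    if p1_idx + 1 >= sm.size:
        raise ValueError("no samples after P1 inside the window; cannot define N1")
    n1_idx = p1_idx + 1 + int(np.argmin(sm[p1_idx + 1 :]))
    n1_amp = float(seg[n1_idx])
    n1_latency_ms = (i0 + n1_idx - stim_onset_index) / fs * 1000.0

    return SSEPResult(
        p1_latency_ms=p1_latency_ms,
        p1_amp_uV=p1_amp,
        n1_latency_ms=n1_latency_ms,
        n1_amp_uV=n1_amp,
        amplitude_pp_uV=p1_amp - n1_amp,
        latency_ms=p1_latency_ms,
    )
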