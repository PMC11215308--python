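"""Cortical spreading depression (CSD) event detection and velocity.

CSD transients appear in a normalized rCBF trace as large hyperemic
peaks (tens of percent above baseline) riding on vasomotion and
measurement noise.  Detection is prominence-based local-maximum finding
with a refractory period (CSD waves cannot recur arbitrarily fast), a
light moving-average pre-smoothing, and quadratic sub-sample refinement
of each peak time — the hyperemic peak, not the preceding dip, defines
event timing.

Propagation velocity comes from two ROIs a known distance apart:
``velocity = 60 * distance_mm / dt_s`` (mm/min) with ``dt`` the delay
between matched hyperemic peaks, matched in order of occurrence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import NormalizedTrace

__all__ = [
    "CSDEvent",
    "CSDEventList",
    "VelocityEstimate",
    "detect_csd_events",
    "count_events",
    "point_distance",
    "csd_velocity",
]


@dataclass
class CSDEvent:
    peak_time_s: float
    peak_value: float  # rCBF_N units
    prominence: float  # rCBF_N units
    onset_time_s: float
    recovered: bool  # trace back within tolerance of baseline after the event

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValueError("prominence must be positive")
        if self.onset_time_s > self.peak_time_s:
            raise ValueError("onset must not follow the peak")


@dataclass
class CSDEventList:
    events: list[CSDEvent]
    trace_id: str = ""
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [e.peak_time_s for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class VelocityEstimate:
    """Two-point CSD propagation velocity (first matched peak pair)."""

    p1_xy_mm: tuple[float, float]
    p2_xy_mm: tuple[float, float]
    distance_mm: float
    peak_time_1_s: float
    peak_time_2_s: float
    dt_s: float
    velocity_mm_per_min: float
    pair_velocities_mm_per_min: list[float] = field(default_factory=list)
    mean_velocity_mm_per_min: float = float("nan")


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with truncated edges."""
    if width <= 1:
        return x
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _refine_peak(y: np.ndarray, idx: int, half_width: int, fs: float) -> float:
    """Sub-sample peak time from a quadratic fit around a discrete peak."""
    lo = max(0, idx - half_width)
    hi = min(y.size, idx + half_width + 1)
    if hi - lo < 5:
        return idx / fs
    t = np.arange(lo, hi, dtype=float)
    a, b, _ = np.polyfit(t, y[lo:hi], 2)
    if a >= 0:
        return idx / fs
    vertex = -b / (2.0 * a)
    if not (lo <= vertex <= hi - 1):
        return idx / fs
    return vertex / fs


def detect_csd_events(
    ntrace: NormalizedTrace,
    min_prominence: float = 0.2,
    refractory_s: float = 120.0,
    *,
    smooth_s: float = 5.0,
    refine_half_width_s: float = 15.0,
    recovery_delay_s: float = 60.0,
    recovery_window_s: float = 60.0,
    recovery_tol: float = 0.05,
    trace_id: str = "",
) -> CSDEventList:
    """Detect CSD transients as prominent local maxima.

    Peaks must have prominence >= ``min_prominence`` (rCBF_N units,
    interpreted relative to the trace's baseline-window level so
    detection is invariant to positive rescaling) and be separated by
    at least ``refractory_s``.  The trace is lightly smoothed (moving average of
    ``smooth_s``) before peak finding and each peak time is refined by a
    quadratic fit over +/- ``refine_half_width_s``.

    An event is flagged ``recovered`` when the trace median over the
    window ``[peak + recovery_delay_s, peak + recovery_delay_s +
    recovery_window_s]`` lies within ``recovery_tol`` of the baseline
    level (a non-recovering oligemic plateau fails this).
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    fs = ntrace.sampling_rate_hz
    v = ntrace.rcbf_n
    if v.size / fs < refractory_s:
        raise ValueError("trace shorter than the refractory period")

    # baseline level from the trace's own baseline window (not the global
    # median: a long post-event oligemic plateau would drag the median
    # down and mask non-recovery); keeps detection scale-invariant
    b0 = int(round(ntrace.baseline_window[0] * fs))
    b1 = min(int(round(ntrace.baseline_window[1] * fs)), v.size)
    level = float(np.mean(v[b0:b1])) if b1 > b0 else float(np.median(v))
    if level <= 0:
        raise ValueError("trace baseline level must be positive for normalized detection")
    smooth_w = max(1, int(round(smooth_s * fs)) | 1)
    w = _moving_average(v, smooth_w)

    distance = max(1, int(round(refractory_s * fs)))
    peaks, props = find_peaks(w, prominence=min_prominence * level, distance=distance)

    half = int(round(refine_half_width_s * fs))
    events: list[CSDEvent] = []
    n = v.size
    for j, idx in enumerate(peaks):
        peak_time = _refine_peak(w, int(idx), half, fs)
        onset_time = props["left_bases"][j] / fs
        # recovery: median of the raw trace in a window after the transient
        r0 = int(round((peak_time + recovery_delay_s) * fs))
        r1 = int(round((peak_time + recovery_delay_s + recovery_window_s) * fs))
        if r0 >= n:  # event too close to the end: judge from the tail
            r0 = max(0, n - int(round(recovery_window_s * fs)))
            r1 = n
        r1 = min(r1, n)
        post_median = float(np.median(v[r0:r1]))
        recovered = abs(post_median / level - 1.0) <= recovery_tol
        events.append(
            CSDEvent(
                peak_time_s=float(peak_time),
                peak_value=float(v[idx]),
                prominence=float(props["prominences"][j]),
                onset_time_s=float(min(onset_time, peak_time)),
                recovered=recovered,
            )
        )
    params = dict(
        min_prominence=min_prominence, refractory_s=refractory_s, smooth_s=smooth_s,
        refine_half_width_s=refine_half_width_s, recovery_delay_s=recovery_delay_s,
        recovery_window_s=recovery_window_s, recovery_tol=recovery_tol,
    )
    return CSDEventList(events=events, trace_id=trace_id, detection_params=params)


def count_events(events: CSDEventList) -> int:
    """Number of detected CSD events."""
    return len(events)


def point_distance(p1_xy_mm: tuple[float, float], p2_xy_mm: tuple[float, float]) -> float:
    """Euclidean distance between two marked cortical points (mm)."""
    d = math.hypot(p1_xy_mm[0] - p2_xy_mm[0], p1_xy_mm[1] - p2_xy_mm[1])
    if d == 0:
        raise ValueError("points coincide; propagation velocity is undefined")
    return d


def csd_velocity(
    events_a: CSDEventList,
    events_b: CSDEventList,
    p1_xy_mm: tuple[float, float],
    p2_xy_mm: tuple[float, float],
    *,
    min_plausible_velocity_mm_per_min: float = 1.0,
) -> VelocityEstimate:
    """Propagation velocity from peak delays between two ROIs.

    Events are paired in order of occurrence (up to the shorter list,
    with a warning on count mismatch).  Pairs whose delay implies a
    velocity below ``min_plausible_velocity_mm_per_min`` are rejected as
    spurious.  The estimate reports the first retained pair plus the
    per-pair velocities and their mean.
    """
    if len(events_a) < 1 or len(events_b) < 1:
        raise ValueError("both event lists must contain at least one event")
    if len(events_a) != len(events_b):
        warnings.warn(
            f"event count mismatch ({len(events_a)} vs {len(events_b)}); "
            "pairing up to the shorter list",
            stacklevel=2,
        )
    dist = point_distance(p1_xy_mm, p2_xy_mm)
    max_dt = dist / min_plausible_velocity_mm_per_min * 60.0

    pairs: list[tuple[float, float]] = []
    for ea, eb in zip(events_a, events_b):
        dt = abs(eb.peak_time_s - ea.peak_time_s)
        if dt == 0:
            raise ValueError("zero peak-time difference; velocity undefined")
        if dt > max_dt:
            warnings.warn(
                f"peak pair with dt = {dt:.1f} s rejected as implausibly slow",
                stacklevel=2,
            )
            continue
        pairs.append((ea.peak_time_s, eb.peak_time_s))
    if not pairs:
        raise ValueError("no plausible peak pairs between the two ROIs")

    velocities = [dist / abs(t2 - t1) * 60.0 for t1, t2 in pairs]
    t1, t2 = pairs[0]
    return VelocityEstimate(
        p1_xy_mm=tuple(p1_xy_mm),
        p2_xy_mm=tuple(p2_xy_mm),
        distance_mm=dist,
        peak_time_1_s=t1,
        peak_time_2_s=t2,
        dt_s=abs(t2 - t1),
        velocity_mm_per_min=velocities[0],
        pair_velocities_mm_per_min=velocities,
        mean_velocity_mm_per_min=float(np.mean(velocities)),
    )
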