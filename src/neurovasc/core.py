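"""Shared in-memory containers for the neurovascular pipeline.

The central raster object is :class:`FlowMovie`, a time-ordered stack of
2-D relative-flow frames with acquisition metadata (frame rate, pixel
size).  One-dimensional signals live in :class:`ROITrace` (mean flow
inside a circular region of interest) and :class:`NormalizedTrace` (the
same trace expressed as rCBF_N, a dimensionless ratio to a resting
baseline).  Stimulation-locked electrophysiology epochs live in
:class:`EpochSet`, longitudinal glucose measurements in
:class:`GlucoseSeries`.

Coordinate convention: image row 0 is the top of the field, x runs along
columns, y along rows, with the origin at the top-left corner of the
image.  Physical coordinates are millimetres; the centre of pixel
(row i, col j) is at ((j + 0.5) * pixel_size_mm, (i + 0.5) * pixel_size_mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FlowMovie",
    "ROISpec",
    "ROITrace",
    "NormalizedTrace",
    "EpochSet",
    "GlucoseSeries",
]


@dataclass
class FlowMovie:
    """Time-ordered stack of 2-D relative flow-index frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_rows, n_cols)``.  Values are a
        relative perfusion index in arbitrary units; NaN marks pixels
        where the flow index is undefined.
    frame_rate_hz
        Acquisition rate in frames per second.
    pixel_size_mm
        Physical size of one pixel in millimetres.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, row, col); got shape {self.frames.shape}"
            )
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def field_size_mm(self) -> tuple[float, float]:
        """(width, height) of the imaged field in mm."""
        _, n_rows, n_cols = self.frames.shape
        return (n_cols * self.pixel_size_mm, n_rows * self.pixel_size_mm)


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest in physical (mm) coordinates."""

    center_xy_mm: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass
class ROITrace:
    """Mean flow index inside an ROI, one value per frame."""

    values: np.ndarray
    sampling_rate_hz: float
    roi: Optional[ROISpec] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("an ROI trace needs at least 2 samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate_hz


@dataclass
class NormalizedTrace:
    """Baseline-normalized rCBF trace (rCBF_N, dimensionless).

    ``rcbf_n[t] = R(t) / R(baseline)`` where ``R(baseline)`` is the mean
    resting flow over ``baseline_window``.  By construction the mean of
    ``rcbf_n`` over the baseline window is 1.
    """

    rcbf_n: np.ndarray
    sampling_rate_hz: float
    baseline_window: tuple[float, float]
    baseline_value: float
    roi: Optional[ROISpec] = None

    def __post_init__(self) -> None:
        self.rcbf_n = np.asarray(self.rcbf_n, dtype=float).ravel()
        if self.rcbf_n.size < 2:
            raise ValueError("normalized trace needs at least 2 samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        lo, hi = self.baseline_window
        if not (0 <= lo < hi):
            raise ValueError("baseline_window must satisfy 0 <= start < end")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.rcbf_n.size) / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return self.rcbf_n.size / self.sampling_rate_hz


@dataclass
class EpochSet:
    """Stimulation-locked electrophysiology epochs.

    ``epochs`` has shape ``(n_epochs, n_samples)`` in microvolts; sample
    ``stim_onset_index`` of each row is the stimulus onset.
    """

    epochs: np.ndarray
    sampling_rate_hz: float
    stim_onset_index: int
    window_s: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if self.epochs.shape[0] < 1:
            raise ValueError("need at least one epoch")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not (0 <= self.stim_onset_index < self.epochs.shape[1]):
            raise ValueError("stim_onset_index must lie inside the epoch window")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        idx = np.arange(self.n_samples) - self.stim_onset_index
        return idx / self.sampling_rate_hz * 1000.0


@dataclass
class GlucoseSeries:
    """Blood glucose levels over a tolerance test (IPGTT / ITT)."""

    times_min: np.ndarray
    values_mg_dl: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float).ravel()
        self.values_mg_dl = np.asarray(self.values_mg_dl, dtype=float).ravel()
        if self.times_min.size != self.values_mg_dl.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if np.any(self.values_mg_dl < 0):
            raise ValueError("glucose values must be non-negative")
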