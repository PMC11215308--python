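"""File formats and the end-to-end pipeline runner.

Flow movies travel as multi-page TIFF with a JSON sidecar carrying the
acquisition metadata (frame_rate_hz, pixel_size_mm, and an optional
config echo).  Traces and epochs are plain CSV with a header row.
``run_pipeline`` ties the stages together in dependency order and
returns a :class:`RunReport` that, together with the echoed config and
seeds, fully reconstructs the run.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile

from . import csd_analysis, metabolic_stats, rcbf_coherence, ssep_analysis, synthetic_data
from .core import EpochSet, FlowMovie, GlucoseSeries, ROISpec, ROITrace

__all__ = [
    "write_flow_movie",
    "read_flow_movie",
    "write_trace",
    "read_trace",
    "write_epochs",
    "read_epochs",
    "write_glucose",
    "read_glucose",
    "PipelineConfig",
    "PipelineStageError",
    "RunReport",
    "run_pipeline",
]

SIDE_CAR_FIELDS = ("frame_rate_hz", "pixel_size_mm")


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_flow_movie(movie: FlowMovie, path: str | Path, extra: Optional[dict] = None) -> Path:
    """Write a flow movie as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta: dict[str, Any] = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_mm": movie.pixel_size_mm,
        "n_frames": movie.n_frames,
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_flow_movie(path: str | Path) -> FlowMovie:
    """Read a multi-page TIFF flow movie with its JSON sidecar.

    Errors name the missing sidecar field; stacks with non-uniform frame
    shapes are rejected.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for fld in SIDE_CAR_FIELDS:
        if fld not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required field '{fld}'")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.dtype == object:
        raise ValueError("TIFF stack must contain uniformly shaped 2-D frames")
    if "n_frames" in meta and int(meta["n_frames"]) != frames.shape[0]:
        raise ValueError(
            f"sidecar declares {meta['n_frames']} frames but the TIFF holds {frames.shape[0]}"
        )
    return FlowMovie(
        frames=np.asarray(frames, dtype=float),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_size_mm=float(meta["pixel_size_mm"]),
    )


def write_trace(trace: ROITrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times_s, "value": trace.values}).to_csv(path, index=False)
    return path


def read_trace(path: str | Path) -> ROITrace:
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} is missing column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace CSV must be uniformly sampled in time")
    return ROITrace(values=df["value"].to_numpy(dtype=float), sampling_rate_hz=1.0 / dt[0])


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Epoch matrix as CSV (one row per epoch) with a JSON sidecar."""
    path = Path(path)
    cols = [f"s{i}" for i in range(epochs.n_samples)]
    pd.DataFrame(epochs.epochs, columns=cols).to_csv(path, index=False)
    meta = {
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "stim_onset_index": epochs.stim_onset_index,
        "window_s": list(epochs.window_s),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    return EpochSet(
        epochs=df.to_numpy(dtype=float),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        stim_onset_index=int(meta["stim_onset_index"]),
        window_s=tuple(meta.get("window_s", (0.0, 0.0))),
    )


def write_glucose(series_list: list[GlucoseSeries], path: str | Path) -> Path:
    """Long-format CSV: subject, condition, time_min, glucose_mg_dl."""
    rows = []
    for s in series_list:
        for t, v in zip(s.times_min, s.values_mg_dl):
            rows.append(
                {"subject": s.subject_id, "condition": s.condition,
                 "time_min": t, "glucose_mg_dl": v}
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_glucose(path: str | Path) -> list[GlucoseSeries]:
    df = pd.read_csv(path)
    for col in ("subject", "condition", "time_min", "glucose_mg_dl"):
        if col not in df.columns:
            raise ValueError(f"glucose CSV {path} is missing column '{col}'")
    out = []
    for (subj, cond), grp in df.groupby(["subject", "condition"], sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            GlucoseSeries(
                times_min=grp["time_min"].to_numpy(dtype=float),
                values_mg_dl=grp["glucose_mg_dl"].to_numpy(dtype=float),
                subject_id=str(subj),
                condition=str(cond),
            )
        )
    return out


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

STAGE_ORDER = ("simulate", "csd", "coherence", "stim", "ssep", "metabolic")


@dataclass
class PipelineConfig:
    """Stage selection plus per-stage parameter blocks.

    ``stages`` is a subset of :data:`STAGE_ORDER` (executed in
    dependency order regardless of listing order); ``params`` holds one
    block per stage.  Every block is validated by the stage's own
    dataclasses before any computation runs.
    """

    stages: list[str] = field(default_factory=list)
    seed: int = 0
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for st in self.stages:
            if st not in STAGE_ORDER:
                raise ValueError(f"unknown stage {st!r}; known stages: {STAGE_ORDER}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name, cause, and partial report."""

    def __init__(self, stage: str, cause: Exception, report: dict):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.report = report


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict[str, dict]
    wall_clock_s: dict[str, float]

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_simulate(params: dict, seed: int, ctx: dict) -> dict:
    waves = [synthetic_data.CSDWaveSpec(**w) for w in params.pop("csd_events", [])]
    cfg = synthetic_data.SimConfig(seed=params.pop("seed", seed),
                                   csd_events=waves, **params)
    ctx["movie"] = synthetic_data.gen_flow_movie(cfg)
    return {"n_frames": ctx["movie"].n_frames, "duration_s": ctx["movie"].duration_s}


def _roi_ntrace(ctx: dict, roi_params: dict, baseline) -> Any:
    movie = ctx["movie"]
    roi = ROISpec(center_xy_mm=tuple(roi_params["center_xy_mm"]),
                  radius_mm=roi_params["radius_mm"])
    trace = rcbf_coherence.extract_roi_trace(movie, roi)
    return rcbf_coherence.normalize_rcbf(trace, tuple(baseline))


def _stage_csd(params: dict, seed: int, ctx: dict) -> dict:
    if "movie" not in ctx:
        raise ValueError("csd stage requires a flow movie (run 'simulate' first or load one)")
    baseline = params.get("baseline_window", (0.0, 60.0))
    det = {k: params[k] for k in ("min_prominence", "refractory_s") if k in params}
    nt_a = _roi_ntrace(ctx, params["roi_a"], baseline)
    nt_b = _roi_ntrace(ctx, params["roi_b"], baseline)
    ev_a = csd_analysis.detect_csd_events(nt_a, **det)
    ev_b = csd_analysis.detect_csd_events(nt_b, **det)
    out: dict[str, Any] = {
        "events_a": [dataclasses.asdict(e) for e in ev_a],
        "events_b": [dataclasses.asdict(e) for e in ev_b],
        "count_a": csd_analysis.count_events(ev_a),
        "count_b": csd_analysis.count_events(ev_b),
    }
    if len(ev_a) and len(ev_b):
        vel = csd_analysis.csd_velocity(
            ev_a, ev_b,
            tuple(params["roi_a"]["center_xy_mm"]),
            tuple(params["roi_b"]["center_xy_mm"]),
        )
        out["velocity"] = dataclasses.asdict(vel)
        out["velocity_units"] = "mm/min"
    return out


def _stage_coherence(params: dict, seed: int, ctx: dict) -> dict:
    if "movie" not in ctx:
        raise ValueError("coherence stage requires a flow movie")
    movie = ctx["movie"]
    roi_a = ROISpec(tuple(params["roi_a"]["center_xy_mm"]), params["roi_a"]["radius_mm"])
    roi_m = ROISpec(tuple(params["roi_m"]["center_xy_mm"]), params["roi_m"]["radius_mm"])
    ta = rcbf_coherence.extract_roi_trace(movie, roi_a)
    tm = rcbf_coherence.extract_roi_trace(movie, roi_m)
    spec = rcbf_coherence.compute_coherence(ta, tm)
    lag = rcbf_coherence.band_phase_lag(
        spec,
        band_hz=tuple(params.get("band_hz", (0.05, 0.15))),
        coh_threshold=params.get("coh_threshold", 0.5),
    )
    return {"lag": dataclasses.asdict(lag), "lag_units": "s"}


def _stage_stim(params: dict, seed: int, ctx: dict) -> dict:
    trace = synthetic_data.gen_stim_trace(
        baseline=params.get("baseline", 100.0),
        plateau_ratio=params.get("plateau_ratio", 1.28),
        pre_s=params.get("pre_s", 10.0),
        stim_s=params.get("stim_s", 40.0),
        post_s=params.get("post_s", 10.0),
        noise_sd=params.get("noise_sd", 0.0),
        seed=params.get("seed", seed),
    )
    pre = (0.0, params.get("pre_s", 10.0))
    nt = rcbf_coherence.normalize_rcbf(trace, pre)
    stim_w = tuple(params.get("stim_window", (pre[1], pre[1] + 30.0)))
    resp = rcbf_coherence.stim_response(nt, stim_w)
    return {"stim_response": dataclasses.asdict(resp), "units": "dimensionless (rCBF_N)"}


def _stage_ssep(params: dict, seed: int, ctx: dict) -> dict:
    cfg = synthetic_data.SSEPSimConfig(seed=params.pop("seed", seed), **params)
    epochs = synthetic_data.gen_ssep_epochs(cfg)
    avg = ssep_analysis.average_epochs(epochs)
    res = ssep_analysis.extract_components(
        avg, epochs.sampling_rate_hz, epochs.stim_onset_index
    )
    return {"ssep": dataclasses.asdict(res),
            "units": {"amplitude": "uV", "latency": "ms"}}


def _stage_metabolic(params: dict, seed: int, ctx: dict) -> dict:
    cfg = synthetic_data.GlucoseSimConfig(seed=params.pop("seed", seed), **params)
    series = synthetic_data.gen_glucose_table(cfg)
    auc = metabolic_stats.auc_trapezoid(series)
    auc_sub = metabolic_stats.auc_trapezoid(series, baseline_subtract=True)
    peak = float(series.values_mg_dl.max())
    return {
        "glucose_mg_dl": series.values_mg_dl.tolist(),
        "times_min": series.times_min.tolist(),
        "auc": dataclasses.asdict(auc),
        "auc_baseline_subtracted": dataclasses.asdict(auc_sub),
        "auc_units": "mg*min/dL",
        "diabetic": metabolic_stats.classify_diabetic(peak),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "csd": _stage_csd,
    "coherence": _stage_coherence,
    "stim": _stage_stim,
    "ssep": _stage_ssep,
    "metabolic": _stage_metabolic,
}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the requested stages in dependency order.

    Identical config (and seeds) implies an identical report apart from
    wall-clock timings.  A stage failure raises
    :class:`PipelineStageError` carrying the partial report with a
    failure marker for the offending stage.
    """
    from . import __version__

    report = RunReport(
        config=dataclasses.asdict(config), version=__version__,
        stages={}, wall_clock_s={},
    )
    ctx: dict[str, Any] = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        params = dict(config.params.get(stage, {}))
        try:
            report.stages[stage] = _STAGE_FUNCS[stage](params, config.seed, ctx)
        except Exception as exc:
            report.stages[stage] = {"status": "failed", "error": str(exc)}
            report.wall_clock_s[stage] = time.perf_counter() - t0
            raise PipelineStageError(stage, exc, dataclasses.asdict(report)) from exc
        report.wall_clock_s[stage] = time.perf_counter() - t0
    return report
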