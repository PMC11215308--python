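"""Metabolic-side computations: glucose AUC, diabetes call, group stats.

The glucose tolerance test samples blood glucose at a handful of
timepoints (0, 30, 60, 120 min by default); its summary statistic is
the trapezoidal area under the glucose curve in mg*min/dL, optionally
after subtracting the fasting (t = 0) level.  Animals are classified
diabetic at a postprandial glucose of 288 mg/dL or above.  Group
summaries report mean/SD/SEM and a Welch unpaired two-sample
comparison; multi-group family corrections (Sidak, Tukey) are thin
pass-throughs to standard routines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import GlucoseSeries

__all__ = [
    "AUCResult",
    "GroupSummary",
    "auc_trapezoid",
    "classify_diabetic",
    "group_summary",
    "sidak_adjust",
    "tukey_hsd",
    "DIABETIC_THRESHOLD_MG_DL",
]

#: postprandial blood glucose at or above this level is called diabetic
DIABETIC_THRESHOLD_MG_DL = 288.0


@dataclass
class AUCResult:
    auc: float  # mg*min/dL
    method: str
    baseline_subtracted: bool


def auc_trapezoid(series: GlucoseSeries, baseline_subtract: bool = False) -> AUCResult:
    """Trapezoidal area under the glucose curve.

    With ``baseline_subtract`` the t = 0 value is subtracted from every
    reading before integration (the incremental AUC); the default
    integrates the raw curve.
    """
    t = series.times_min
    v = series.values_mg_dl
    if t.size < 2:
        raise ValueError("AUC needs at least two timepoints")
    if baseline_subtract:
        v = v - v[0]
    return AUCResult(
        auc=float(np.trapezoid(v, t)),
        method="trapezoid",
        baseline_subtracted=baseline_subtract,
    )


def classify_diabetic(
    postprandial_mg_dl: float, threshold: float = DIABETIC_THRESHOLD_MG_DL
) -> bool:
    """True iff the postprandial glucose level is at or above threshold."""
    if postprandial_mg_dl < 0:
        raise ValueError("glucose level must be non-negative")
    return postprandial_mg_dl >= threshold


@dataclass
class GroupSummary:
    groups: dict[str, dict[str, float]]  # name -> {n, mean, sd, sem}
    mean_difference: Optional[float] = None  # first minus second group
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    comparison: str = ""


def group_summary(values_by_group: Mapping[str, Sequence[float]]) -> GroupSummary:
    """Descriptive statistics per group plus a Welch two-sample test.

    Each group gets n, mean, SD (ddof=1) and SEM.  When exactly two
    groups have n >= 2, a two-sided unpaired Welch t test compares
    them; otherwise the comparison is omitted (descriptives only).
    """
    summ: dict[str, dict[str, float]] = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        entry: dict[str, float] = {"n": float(arr.size), "mean": float(arr.mean())}
        if arr.size >= 2:
            sd = float(arr.std(ddof=1))
            entry["sd"] = sd
            entry["sem"] = sd / np.sqrt(arr.size)
        summ[name] = entry

    out = GroupSummary(groups=summ)
    eligible = [name for name, e in summ.items() if e["n"] >= 2]
    if len(values_by_group) == 2 and len(eligible) == 2:
        a_name, b_name = list(values_by_group.keys())
        a = np.asarray(list(values_by_group[a_name]), dtype=float)
        b = np.asarray(list(values_by_group[b_name]), dtype=float)
        res = stats.ttest_ind(a, b, equal_var=False)
        out.mean_difference = float(a.mean() - b.mean())
        out.t_statistic = float(res.statistic)
        out.p_value = float(res.pvalue)
        out.comparison = f"{a_name} vs {b_name} (Welch unpaired t, two-sided)"
    return out


def sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Sidak family correction (pass-through): 1 - (1 - p)**m."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def tukey_hsd(*groups: Sequence[float]):
    """Tukey honest-significant-difference test (scipy pass-through)."""
    return stats.tukey_hsd(*[np.asarray(list(g), dtype=float) for g in groups])
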