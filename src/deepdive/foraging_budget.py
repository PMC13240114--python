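"""Roll-variance foraging classification and deployment time budgets.

High bottom-phase roll variance is used as a foraging indicator applicable
to tags without audio.  The decision threshold is calibrated against
regular-click labels where available, by minimising the number of
disagreements between the acoustic and kinematic classifications
(clicking-but-quiet-roll plus silent-but-rolling).  A dive is foraging iff
its bottom-phase roll variance strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dive_segmentation import Dive, DiveMetrics
from .errors import CalibrationError, EmptyRecordError
from .tag_io import TagSeries

__all__ = [
    "ForagingModel",
    "TimeBudget",
    "calibrate_threshold",
    "classify_foraging",
    "foraging_dive_stats",
    "time_budget",
]


@dataclass
class ForagingModel:
    """Calibrated roll-variance cutoff with its mismatch diagnostics."""

    threshold: float
    n_mismatch: int
    confusion: dict[str, int]  # click_forage, click_nonforage, silent_forage, silent_nonforage
    curve: pd.DataFrame  # candidate threshold -> mismatches


@dataclass
class TimeBudget:
    """Percentages of analysed deployment time (surface / foraging / bottom)."""

    deployment_id: str
    location: str
    pct_surface: float
    pct_all_dives: float
    pct_foraging_dives: float
    pct_bottom_foraging: float


def calibrate_threshold(roll_vars, click_labels) -> ForagingModel:
    """Find the roll-variance cutoff that minimises click/roll disagreement.

    Candidate thresholds are the midpoints between consecutive sorted
    unique roll variances, plus the interval endpoints 0 and 1 (so the
    degenerate "everything foraging"/"nothing foraging" optima remain
    representable).  The mismatch objective is piecewise constant in the
    threshold; ties resolve to the smallest candidate.  Dives with missing
    labels or roll variances are ignored; calibration requires both classes.
    """
    rv = np.asarray(roll_vars, dtype=float)
    labels = np.asarray([bool(c) if c is not None else None for c in click_labels], dtype=object)
    ok = np.array([lab is not None and np.isfinite(v) for v, lab in zip(rv, labels)])
    rv, clicks = rv[ok], labels[ok].astype(bool)
    if rv.size == 0 or clicks.all() or (~clicks).all():
        raise CalibrationError("calibration needs clicking and silent dives")
    uniq = np.unique(rv)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    # mismatches: clicking dives classed non-foraging (rv <= th)
    #           + silent dives classed foraging (rv > th)
    mism = np.array(
        [int(np.sum(clicks & (rv <= th)) + np.sum(~clicks & (rv > th))) for th in candidates]
    )
    i = int(np.argmin(mism))  # argmin returns the first (smallest) candidate
    th = float(candidates[i])
    forage = rv > th
    confusion = {
        "click_forage": int(np.sum(clicks & forage)),
        "click_nonforage": int(np.sum(clicks & ~forage)),
        "silent_forage": int(np.sum(~clicks & forage)),
        "silent_nonforage": int(np.sum(~clicks & ~forage)),
    }
    curve = pd.DataFrame({"threshold": candidates, "mismatches": mism})
    return ForagingModel(th, int(mism[i]), confusion, curve)


def classify_foraging(metrics: list[DiveMetrics], threshold: float) -> np.ndarray:
    """Foraging iff bottom-phase roll variance strictly exceeds the cutoff.

    Dives with missing bottom metrics (V-shaped dives) are non-foraging.
    """
    rv = np.array([m.roll_var_bottom for m in metrics], dtype=float)
    out = np.zeros(len(metrics), dtype=bool)
    finite = np.isfinite(rv)
    out[finite] = rv[finite] > threshold
    return out


def foraging_dive_stats(
    dives: list[Dive], metrics: list[DiveMetrics], labels
) -> pd.DataFrame:
    """Per-foraging-dive characteristics including diving efficiency.

    Diving efficiency is bottom duration / (dive duration + post-dive time
    until the next foraging dive); the last foraging dive of a deployment
    is excluded because its post-dive time is unobserved.  Deployments with
    fewer than two foraging dives yield an empty table.
    """
    order = np.argsort([d.start_s for d in dives])
    rows = []
    fidx = [i for i in order if labels[i]]
    for a, b in zip(fidx, fidx[1:]):
        d, m = dives[a], metrics[a]
        bottom_s = max(0.0, (d.t_asc_start or d.start_s) - (d.t_desc_end or d.start_s))
        cycle_s = dives[b].start_s - d.start_s
        rows.append(
            {
                "deployment_id": d.deployment_id,
                "location": m.location,
                "dive_id": d.dive_id,
                "head_var_bottom": m.head_var_bottom,
                "jerk_cv_bottom": m.jerk_cv_bottom,
                "pct_bottom": m.pct_bottom,
                "diving_efficiency": bottom_s / cycle_s if cycle_s > 0 else np.nan,
            }
        )
    cols = [
        "deployment_id",
        "location",
        "dive_id",
        "head_var_bottom",
        "jerk_cv_bottom",
        "pct_bottom",
        "diving_efficiency",
    ]
    return pd.DataFrame(rows, columns=cols)


def time_budget(series: TagSeries, dives: list[Dive], labels) -> TimeBudget:
    """Percentages of the analysed record at surface, in foraging dives and
    in the bottom phase of foraging dives.

    Surface time is the complement of all dive spans, so
    ``pct_surface + pct_all_dives == 100`` by construction.
    """
    duration = series.duration_s
    if duration <= 0:
        raise EmptyRecordError("zero-length record")
    dive_s = sum(d.end_s - d.start_s for d in dives)
    forage_s = sum(d.end_s - d.start_s for d, lab in zip(dives, labels) if lab)
    bottom_s = sum(
        max(0.0, (d.t_asc_start or 0.0) - (d.t_desc_end or 0.0))
        for d, lab in zip(dives, labels)
        if lab and d.t_desc_end is not None
    )
    return TimeBudget(
        deployment_id=series.deployment_id,
        location=series.location,
        pct_surface=100.0 * (duration - dive_s) / duration,
        pct_all_dives=100.0 * dive_s / duration,
        pct_foraging_dives=100.0 * forage_s / duration,
        pct_bottom_foraging=100.0 * bottom_s / duration,
    )
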