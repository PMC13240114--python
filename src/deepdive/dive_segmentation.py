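"""Dive detection, pitch-based phase segmentation and per-dive metrics.

A submergence deeper than the dive threshold (default 40 m) is a dive.  Its
span runs from the last upward crossing of the near-surface band (default
5 m) before the threshold is exceeded to the next return into the band,
with crossing times linearly interpolated between samples.  Phases follow
the pitch convention: the bottom phase is the time from the end of the
descent (pitch first exceeds 0 deg) until the start of the ascent (pitch
last below 0 deg); pitch is smoothed (default 5 s) before the sign tests.
Samples at a boundary belong to the later phase (half-open convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientDataError, UndefinedStatisticError
from .kinematics import JerkSeries, OrientationSeries, circular_variance, jerk_cv
from .tag_io import TagSeries

__all__ = [
    "Dive",
    "DiveMetrics",
    "detect_dives",
    "segment_phases",
    "dive_metrics",
    "surface_intervals",
]


@dataclass
class Dive:
    """A detected submergence with (optional) phase boundaries."""

    deployment_id: str
    dive_id: int
    start_s: float
    end_s: float
    max_depth_m: float
    complete: bool
    t_desc_end: float | None = None
    t_asc_start: float | None = None
    flagged: bool = False  # pitch-based segmentation looked unreliable

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0


@dataclass
class DiveMetrics:
    """Clustering and foraging feature vector for one complete dive.

    Bottom-phase statistics are NaN (missing, not 0) for V-shaped dives
    with an empty bottom phase.  ``has_clicks`` is None when the tag had no
    acoustic coverage.
    """

    deployment_id: str
    dive_id: int
    location: str
    max_depth_m: float
    duration_min: float
    descent_rate_ms: float
    ascent_rate_ms: float
    roll_var_bottom: float
    head_var_bottom: float
    jerk_cv_bottom: float
    pct_bottom: float
    has_clicks: bool | None

    @property
    def duration_s(self) -> float:
        return self.duration_min * 60.0

    def feature_vector(self) -> np.ndarray:
        """Unscaled K-means features: duration (s), depth (m), rates (m/s)."""
        return np.array(
            [self.duration_s, self.max_depth_m, self.ascent_rate_ms, self.descent_rate_ms]
        )


def _cross_time(t0, d0, t1, d1, level):
    """Linear interpolation of the time depth crosses ``level``."""
    if d1 == d0:
        return t0
    return t0 + (level - d0) * (t1 - t0) / (d1 - d0)


def detect_dives(
    series: TagSeries,
    threshold_m: float = 40.0,
    surface_band_m: float = 5.0,
    min_duration_s: float = 60.0,
) -> list[Dive]:
    """Detect dives as near-surface-band excursions exceeding ``threshold_m``.

    Submergences that never cross the threshold, or that last less than
    ``min_duration_s`` (pressure spikes), are ignored.  Excursions truncated
    by a record edge or a sensor gap are marked incomplete.
    """
    dives: list[Dive] = []
    k = 0
    for seg in series.segments():
        t = series.t[seg]
        depth = series.depth[seg]
        sub = depth >= surface_band_m
        if not np.any(sub):
            continue
        padded = np.r_[0, sub.view(np.int8), 0]
        edges = np.flatnonzero(np.diff(padded))
        for i0, i1 in zip(edges[0::2], edges[1::2]):  # [i0, i1) submerged
            if np.max(depth[i0:i1]) <= threshold_m:
                continue
            start_complete = i0 > 0
            end_complete = i1 < len(depth)
            start_s = (
                _cross_time(t[i0 - 1], depth[i0 - 1], t[i0], depth[i0], surface_band_m)
                if start_complete
                else float(t[i0])
            )
            end_s = (
                _cross_time(t[i1 - 1], depth[i1 - 1], t[i1], depth[i1], surface_band_m)
                if end_complete
                else float(t[i1 - 1])
            )
            if end_s - start_s < min_duration_s:
                continue
            dives.append(
                Dive(
                    deployment_id=series.deployment_id,
                    dive_id=k,
                    start_s=float(start_s),
                    end_s=float(end_s),
                    max_depth_m=float(np.max(depth[i0:i1])),
                    complete=start_complete and end_complete,
                )
            )
            k += 1
    return dives


def segment_phases(
    dive: Dive, orientation: OrientationSeries, smooth_s: float = 5.0
) -> tuple[float, float]:
    """Locate the descent/bottom and bottom/ascent boundaries by pitch sign.

    On pitch smoothed over ``smooth_s``: the descent ends at the first
    in-dive sample with pitch > 0 and the ascent starts at the last sample
    with pitch < 0.  If the first crossing comes after the last (a V-shaped
    dive) the bottom phase is empty and both boundaries collapse onto the
    single zero crossing.  The dive is flagged (with a warning) if pitch is
    never negative early in the dive.
    """
    sel = (orientation.t >= dive.start_s) & (orientation.t <= dive.end_s)
    idx = np.flatnonzero(sel)
    if idx.size < 3:
        raise InsufficientDataError("orientation does not cover the dive span")
    pitch = orientation.pitch[idx]
    win = max(1, int(round(smooth_s * orientation.fs)))
    win += win % 2 == 0
    if win > 1:
        pitch = uniform_filter1d(pitch, win, mode="nearest")
    t = orientation.t[idx]

    early = pitch[: max(3, idx.size // 4)]
    if not np.any(early < 0):
        warnings.warn(
            f"dive {dive.dive_id}: pitch never negative during descent span",
            RuntimeWarning,
            stacklevel=2,
        )
        dive.flagged = True

    pos = np.flatnonzero(pitch > 0)
    neg = np.flatnonzero(pitch < 0)
    if pos.size == 0 or neg.size == 0:
        # monotone-signed pitch: degenerate, collapse on mid-dive
        mid = float(t[len(t) // 2])
        dive.t_desc_end = dive.t_asc_start = mid
        dive.flagged = True
        return mid, mid
    t_desc_end = float(t[pos[0]])
    t_asc_start = float(t[neg[-1]])
    if t_desc_end > t_asc_start:  # V-shaped dive: empty bottom phase
        sign_change = np.flatnonzero(np.diff(np.sign(pitch)) > 0)
        cross = float(t[sign_change[0] + 1]) if sign_change.size else t_desc_end
        t_desc_end = t_asc_start = cross
    dive.t_desc_end = t_desc_end
    dive.t_asc_start = t_asc_start
    return t_desc_end, t_asc_start


def _interp_depth(series: TagSeries, time_s: float) -> float:
    return float(np.interp(time_s, series.t, series.depth))


def dive_metrics(
    dive: Dive,
    series: TagSeries,
    orientation: OrientationSeries,
    jerk: JerkSeries,
) -> DiveMetrics:
    """Compute the clustering + foraging feature vector for a complete dive.

    Descent rate is the depth gained between the dive start and the end of
    descent over that interval (ascent analogous, absolute value).
    Circular variances and jerk CV are computed over bottom-phase samples
    only; an empty bottom phase yields NaNs.
    """
    if not dive.complete:
        raise InsufficientDataError("metrics are defined for complete dives only")
    if dive.t_desc_end is None or dive.t_asc_start is None:
        raise InsufficientDataError("segment_phases must run before dive_metrics")
    t1, t2 = dive.t_desc_end, dive.t_asc_start
    desc_dur = t1 - dive.start_s
    asc_dur = dive.end_s - t2
    descent_rate = (_interp_depth(series, t1) - _interp_depth(series, dive.start_s)) / desc_dur
    ascent_rate = abs(_interp_depth(series, t2) - _interp_depth(series, dive.end_s)) / asc_dur

    roll_var = head_var = jcv = np.nan
    bottom_dur = max(0.0, t2 - t1)
    if bottom_dur > 0:
        sel = (orientation.t >= t1) & (orientation.t < t2)
        if np.count_nonzero(sel) >= 2:
            roll_var = circular_variance(orientation.roll[sel])
            head_var = circular_variance(orientation.heading[sel])
        try:
            jcv = jerk_cv(jerk, (t1, t2))
        except (InsufficientDataError, UndefinedStatisticError):
            jcv = np.nan

    has_clicks: bool | None
    if series.click_bouts is None:
        has_clicks = None
    else:
        has_clicks = any(s < dive.end_s and e > dive.start_s for s, e in series.click_bouts)

    return DiveMetrics(
        deployment_id=dive.deployment_id,
        dive_id=dive.dive_id,
        location=series.location,
        max_depth_m=dive.max_depth_m,
        duration_min=dive.duration_min,
        descent_rate_ms=float(descent_rate),
        ascent_rate_ms=float(ascent_rate),
        roll_var_bottom=float(roll_var),
        head_var_bottom=float(head_var),
        jerk_cv_bottom=float(jcv),
        pct_bottom=float(bottom_dur / (dive.end_s - dive.start_s)),
        has_clicks=has_clicks,
    )


def surface_intervals(series: TagSeries, dives: list[Dive]) -> list[tuple[float, float]]:
    """Complement of the dive spans within the record (per segment).

    Zero-length intervals between back-to-back dives are kept so that dive
    time plus surface time partitions the record exactly.
    """
    intervals: list[tuple[float, float]] = []
    dives = sorted(dives, key=lambda d: d.start_s)
    for seg in series.segments():
        t0, t1 = float(series.t[seg.start]), float(series.t[seg.stop - 1])
        cursor = t0
        for d in dives:
            if d.end_s < t0 or d.start_s > t1:
                continue
            intervals.append((cursor, max(cursor, d.start_s)))
            cursor = min(d.end_s, t1)
        intervals.append((cursor, t1))
    return intervals
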