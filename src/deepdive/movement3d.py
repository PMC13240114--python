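"""Dead-reckoned pseudo-tracks, depth-band tortuosity and gyration events.

Pseudo-tracks integrate the body pointing angle at an assumed constant
speed (default 2 m s^-1) or the measured paddlewheel speed; depth comes
from the pressure sensor, not from integration.  Tortuosity index
TI = 1 - net/total horizontal distance, so TI = 0 is straight-line
movement and TI = 1 a perfectly closed loop.  Gyrations are continuous
rotations of at least two full turns — roll during descent, heading during
ascent — detected on the unwrapped angle with a bounded-reversal scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
from scipy.ndimage import uniform_filter1d

from .dive_segmentation import Dive
from .errors import UndefinedStatisticError
from .kinematics import OrientationSeries, circular_variance
from .tag_io import TagSeries

_log = logging.getLogger(__name__)

__all__ = [
    "Track",
    "BandProfile",
    "GyrationEvent",
    "dead_reckon",
    "tortuosity_index",
    "band_profiles",
    "detect_gyrations",
]


@dataclass
class Track:
    """Dead-reckoned pseudo-track: x east, y north (m), z sensor depth."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    speed_used: float | np.ndarray


@dataclass
class BandProfile:
    """Tortuosity and roll variance within one depth band of one phase."""

    deployment_id: str
    dive_id: int | None  # None for surface strata
    phase: str  # descent | ascent | surface
    band_lo: float
    band_hi: float
    ti: float
    roll_var: float
    n_samples: int


@dataclass
class GyrationEvent:
    deployment_id: str
    dive_id: int
    phase: str  # descent | ascent
    axis: str  # roll | heading
    start_s: float
    end_s: float
    n_rotations: int
    direction: int


def dead_reckon(
    orientation: OrientationSeries,
    depth: np.ndarray,
    speed: float | np.ndarray = 2.0,
) -> Track:
    """Integrate pointing angle into a horizontal pseudo-track.

    Per step, horizontal displacement is speed x cos(pitch) x dt along the
    heading (dx east = ... sin(heading), dy north = ... cos(heading)); the
    vertical coordinate is taken from the depth sensor.  The track starts
    at the origin; positions accumulate forward-Euler style, so additive
    dead-reckoning drift is expected with record length.
    """
    v = np.broadcast_to(np.asarray(speed, dtype=float), orientation.pitch.shape)
    if np.any(v <= 0):
        raise ValueError("speed must be positive")
    dt = 1.0 / orientation.fs
    h = v * np.cos(orientation.pitch) * dt
    dx = h * np.sin(orientation.heading)
    dy = h * np.cos(orientation.heading)
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    return Track(orientation.t, x, y, np.asarray(depth, float), speed)


def tortuosity_index(x, y) -> float:
    """TI = 1 - (net horizontal displacement / total horizontal path).

    0 for straight-line movement, 1 for a perfectly closed loop.  Undefined
    (raises) for a stationary or purely vertical segment.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    steps = np.hypot(np.diff(x), np.diff(y))
    total = float(np.sum(steps))
    if total <= 0.0:
        raise UndefinedStatisticError("tortuosity undefined for zero horizontal path")
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return float(min(max(1.0 - net / total, 0.0), 1.0))


def band_profiles(
    series: TagSeries,
    orientation: OrientationSeries,
    track: Track,
    dives: list[Dive],
    band_width_m: float = 50.0,
    min_samples: int = 5,
) -> list[BandProfile]:
    """Per-50-m-band tortuosity and roll variance for descent and ascent,
    plus one pooled profile per surface interval.

    Samples are assigned to bands [k*w, (k+1)*w) by sensor depth, separately
    within each dive's descent and ascent; bands holding fewer than
    ``min_samples`` samples are omitted.  Surface strata are the between-dive
    spans (everything outside dive spans).
    """
    profiles: list[BandProfile] = []
    t = series.t
    in_dive = np.zeros(series.n, dtype=bool)
    for d in dives:
        sel = (t >= d.start_s) & (t <= d.end_s)
        in_dive |= sel
        if d.t_desc_end is None:
            continue
        for phase, lo_t, hi_t in (
            ("descent", d.start_s, d.t_desc_end),
            ("ascent", d.t_asc_start, d.end_s),
        ):
            psel = np.flatnonzero((t >= lo_t) & (t < hi_t))
            if psel.size == 0:
                continue
            bands = np.floor(series.depth[psel] / band_width_m).astype(int)
            for b in np.unique(bands):
                idx = psel[bands == b]
                if idx.size < min_samples:
                    _log.debug(
                        "%s dive %d %s band %d-%d m omitted (%d samples < %d)",
                        series.deployment_id, d.dive_id, phase,
                        b * band_width_m, (b + 1) * band_width_m, idx.size, min_samples,
                    )
                    continue
                try:
                    ti = tortuosity_index(track.x[idx], track.y[idx])
                except UndefinedStatisticError:
                    continue
                profiles.append(
                    BandProfile(
                        deployment_id=series.deployment_id,
                        dive_id=d.dive_id,
                        phase=phase,
                        band_lo=float(b * band_width_m),
                        band_hi=float((b + 1) * band_width_m),
                        ti=ti,
                        roll_var=circular_variance(orientation.roll[idx]),
                        n_samples=int(idx.size),
                    )
                )
    # surface strata: contiguous runs of out-of-dive samples
    out = ~in_dive
    padded = np.r_[0, out.view(np.int8), 0]
    edges = np.flatnonzero(np.diff(padded))
    for i0, i1 in zip(edges[0::2], edges[1::2]):
        if i1 - i0 < min_samples:
            continue
        idx = np.arange(i0, i1)
        try:
            ti = tortuosity_index(track.x[idx], track.y[idx])
        except UndefinedStatisticError:
            continue
        profiles.append(
            BandProfile(
                deployment_id=series.deployment_id,
                dive_id=None,
                phase="surface",
                band_lo=0.0,
                band_hi=float("nan"),
                ti=ti,
                roll_var=circular_variance(orientation.roll[idx]),
                n_samples=int(idx.size),
            )
        )
    return profiles


def _monotone_runs(u: np.ndarray, tol: float):
    """Maximal runs advancing monotonically up to reversals < ``tol`` (rad).

    Yields ``(start_idx, end_idx, delta)`` where delta is the signed
    cumulative rotation of the run.
    """
    runs = []
    n = len(u)
    if n < 2:
        return runs
    direction = 0
    lo = hi = u[0]
    lo_i = hi_i = 0
    start = ext_i = 0
    ext = u[0]
    for i in range(1, n):
        v = u[i]
        if direction == 0:
            if v > hi:
                hi, hi_i = v, i
            if v < lo:
                lo, lo_i = v, i
            if hi - lo > tol:
                direction = 1 if hi_i > lo_i else -1
                start = lo_i if direction > 0 else hi_i
                ext, ext_i = (hi, hi_i) if direction > 0 else (lo, lo_i)
        elif direction > 0:
            if v > ext:
                ext, ext_i = v, i
            elif ext - v > tol:
                runs.append((start, ext_i, u[ext_i] - u[start]))
                direction, start = -1, ext_i
                ext, ext_i = v, i
        else:
            if v < ext:
                ext, ext_i = v, i
            elif v - ext > tol:
                runs.append((start, ext_i, u[ext_i] - u[start]))
                direction, start = 1, ext_i
                ext, ext_i = v, i
    if direction != 0:
        runs.append((start, ext_i, u[ext_i] - u[start]))
    return runs


def detect_gyrations(
    orientation: OrientationSeries,
    dives: list[Dive],
    deployment_id: str = "",
    min_rotations: int = 2,
    reversal_tol_deg: float = 45.0,
    smooth_s: float = 0.5,
) -> list[GyrationEvent]:
    """Detect continuous >= ``min_rotations``-turn rotations.

    Scans roll over each dive's descent span and heading over each ascent
    span (the reported phase/axis pairing).  The angle is unwrapped within
    the span; runs are located on a lightly smoothed copy (gyrations are
    slow relative to sensor noise, so smoothing stops noise from faking a
    > ``reversal_tol_deg`` reversal mid-rotation) while the cumulative
    rotation is read off the raw unwrapped angle at the run endpoints.
    A run counts while the cumulative rotation keeps one sign up to brief
    reversals below the tolerance; ``n_rotations`` is the number of
    completed full turns, floor(|delta| / 360 deg).
    """
    tol = np.deg2rad(reversal_tol_deg)
    events: list[GyrationEvent] = []
    t = orientation.t
    for d in dives:
        if d.t_desc_end is None:
            continue
        for phase, axis, angles, lo_t, hi_t in (
            ("descent", "roll", orientation.roll, d.start_s, d.t_desc_end),
            ("ascent", "heading", orientation.heading, d.t_asc_start, d.end_s),
        ):
            idx = np.flatnonzero((t >= lo_t) & (t < hi_t))
            if idx.size < 3:
                continue
            u = np.unwrap(angles[idx])
            win = max(1, int(round(smooth_s * orientation.fs)))
            win += win % 2 == 0
            u_s = uniform_filter1d(u, min(win, idx.size), mode="nearest") if win > 1 else u
            for i0, i1, _delta_s in _monotone_runs(u_s, tol):
                delta = u[i1] - u[i0]
                n_rot = int(np.floor(abs(delta) / (2.0 * np.pi)))
                if n_rot >= min_rotations:
                    events.append(
                        GyrationEvent(
                            deployment_id=deployment_id or d.deployment_id,
                            dive_id=d.dive_id,
                            phase=phase,
                            axis=axis,
                            start_s=float(t[idx[i0]]),
                            end_s=float(t[idx[i1]]),
                            n_rotations=n_rot,
                            direction=int(np.sign(delta)),
                        )
                    )
    return events
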