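"""Whale-frame orientation, jerk and circular statistics.

Orientation (pitch, roll, heading) is recovered from the low-pass-filtered
gravity component of the accelerometer and the tilt-compensated
magnetometer.  Conventions: pitch positive nose-up in [-pi/2, pi/2] (descent
is negative), roll and heading wrapped to (-pi, pi], heading 0 = north and
clockwise positive.  A level whale reads accel (0, 0, g); a vertical nose-down
descent reads (-g, 0, 0) and pitch -90 deg.

Magnetic declination is deliberately omitted: every downstream use of
heading is a variance, difference or closed-loop displacement, in which a
constant offset cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientDataError, UndefinedStatisticError
from .tag_io import TagSeries

__all__ = [
    "GRAVITY",
    "OrientationSeries",
    "JerkSeries",
    "wrap_angle",
    "angle_difference",
    "estimate_orientation",
    "circular_variance",
    "compute_jerk",
    "jerk_cv",
]

GRAVITY = 9.81  # m s^-2


def wrap_angle(a):
    """Wrap angles (rad) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = (a + np.pi) % (2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def angle_difference(a, b):
    """Smallest signed difference a - b on the circle (rad)."""
    return wrap_angle(np.asarray(a, float) - np.asarray(b, float))


@dataclass
class OrientationSeries:
    """Pitch/roll/heading (rad) on the tag's sample grid."""

    t: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    heading: np.ndarray
    fs: float
    low_gravity: np.ndarray | None = None  # samples where |a_lp| < 0.5 g

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass
class JerkSeries:
    """Norm of the acceleration first difference, scaled to m s^-3."""

    t: np.ndarray
    jerk: np.ndarray
    fs: float


def _odd_window(smooth_s: float, fs: float) -> int:
    w = max(1, int(round(smooth_s * fs)))
    return w if w % 2 == 1 else w + 1


def estimate_orientation(series: TagSeries, smooth_s: float = 3.0) -> OrientationSeries:
    """Estimate pitch, roll and heading from whale-frame accel and mag.

    A zero-phase moving average over ``smooth_s`` seconds separates the
    gravity (posture) component from propulsion before the angles are
    formed:  pitch = asin(ax/|a|), roll = atan2(ay, az), heading from the
    tilt-compensated magnetic vector.  Samples where the filtered
    acceleration norm stays below 0.5 g (dynamic acceleration dominating)
    are flagged and a quality warning is emitted if the condition is
    sustained for more than a second.
    """
    n = series.n
    pitch = np.empty(n)
    roll = np.empty(n)
    heading = np.empty(n)
    low = np.zeros(n, dtype=bool)
    win = _odd_window(smooth_s, series.fs)
    for seg in series.segments():
        A = series.accel[seg]
        M = series.mag[seg]
        if win > 1:
            A = uniform_filter1d(A, win, axis=0, mode="nearest")
            M = uniform_filter1d(M, win, axis=0, mode="nearest")
        norm = np.linalg.norm(A, axis=1)
        seg_low = norm < 0.5 * GRAVITY
        low[seg] = seg_low
        safe = np.where(norm > 1e-12, norm, 1.0)
        p = np.arcsin(np.clip(A[:, 0] / safe, -1.0, 1.0))
        r = np.arctan2(A[:, 1], A[:, 2])
        # sensor frame (x fwd, y left, z up) -> body NED frame, then de-tilt
        bx, by, bz = M[:, 0], -M[:, 1], -M[:, 2]
        sp, cp = np.sin(p), np.cos(p)
        sr, cr = np.sin(r), np.cos(r)
        m1x = bx
        m1y = cr * by - sr * bz
        m1z = sr * by + cr * bz
        mhx = cp * m1x + sp * m1z
        mhy = m1y
        h = np.arctan2(-mhy, mhx)
        pitch[seg], roll[seg], heading[seg] = p, wrap_angle(r), wrap_angle(h)
    if np.any(low):
        # sustained = any run of >= fs samples (one second)
        padded = np.r_[0, low.view(np.int8), 0]
        edges = np.flatnonzero(np.diff(padded))
        runs = edges[1::2] - edges[0::2]
        if runs.size and runs.max() >= series.fs:
            warnings.warn(
                "dynamic acceleration dominates gravity for >1 s; orientation flagged",
                RuntimeWarning,
                stacklevel=2,
            )
    return OrientationSeries(series.t, pitch, roll, heading, series.fs, low)


def circular_variance(angles) -> float:
    """Circular variance 1 - Rbar of a sample of angles (rad).

    Rbar is the mean resultant length of the unit vectors at the given
    angles; the value is 0 for identical angles and 1 for perfectly
    dispersed ones.  Requires at least two finite angles.
    """
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise InsufficientDataError("circular variance needs >= 2 finite angles")
    rbar = np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a)))
    return float(min(max(1.0 - rbar, 0.0), 1.0))


def compute_jerk(series: TagSeries) -> JerkSeries:
    """Jerk as the norm of the accel first difference times fs (m s^-3).

    The jerk sample at ``t[i+1]`` is ``|a[i+1] - a[i]| * fs``; gaps between
    segments are skipped (NaN), so no spurious spikes appear across them.
    """
    if series.n < 2:
        raise InsufficientDataError("jerk needs >= 2 accel samples")
    jerk = np.full(series.n - 1, np.nan)
    for seg in series.segments():
        i0, i1 = seg.start, seg.stop
        if i1 - i0 < 2:
            continue
        d = np.diff(series.accel[i0:i1], axis=0)
        jerk[i0 : i1 - 1] = np.linalg.norm(d, axis=1) * series.fs
    return JerkSeries(series.t[1:], jerk, series.fs)


def jerk_cv(jerk: JerkSeries, window: tuple[float, float]) -> float:
    """Coefficient of variation (sample SD / mean, n-1 denominator) of jerk
    within the half-open time window ``[t0, t1)``.

    Scale-free: rescaling the accelerometer by a positive constant leaves
    the CV unchanged.  Raises if the window holds fewer than two samples or
    the mean jerk is zero (the CV is undefined, not 0).
    """
    t0, t1 = window
    sel = (jerk.t >= t0) & (jerk.t < t1) & np.isfinite(jerk.jerk)
    x = jerk.jerk[sel]
    if x.size < 2:
        raise InsufficientDataError("jerk CV needs >= 2 samples in the window")
    m = float(np.mean(x))
    if m == 0.0:
        raise UndefinedStatisticError("jerk CV undefined: zero mean jerk")
    return float(np.std(x, ddof=1) / m)
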