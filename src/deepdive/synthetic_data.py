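"""Synthetic tag deployments and isotope samples with known ground truth.

The generator builds each dive as descent / bottom / ascent segments whose
maximum depth, duration and vertical rates are truncated-normal draws from a
:class:`DiveTypeSpec` (defaults follow the published per-location dive-type
statistics).  Pitch is steeply negative in descent (-60..-30 deg), crosses
zero exactly at the descent/bottom and bottom/ascent boundaries, and is
positive in ascent, so the pitch-based phase segmentation has an exact
ground truth.  Bottom-phase roll and heading are smooth wrapped processes
calibrated so their empirical circular variance hits the requested
active/quiet level.  Acceleration is gravity rotated by (pitch, roll) plus
optional noise and, in active bottom phases, sparse high-jerk transients;
magnetism is the earth field rotated into the sensor frame (inverse tilt
compensation).  Regular-click bouts span active bottom phases.

Randomness is split into three independent child streams (dive plan, angle
processes, sensor noise) so the dive plan — and therefore dive-level ground
truth — is invariant to the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .errors import SpecError
from .kinematics import GRAVITY, circular_variance, wrap_angle
from .tag_io import TagSeries

__all__ = [
    "DiveTypeSpec",
    "SimTruth",
    "TruthDive",
    "TruthGyration",
    "IsotopeGroupSpec",
    "simulate_deployment",
    "inject_gyration",
    "simulate_isotopes",
    "draw_dive_parameters",
    "JAN_MAYEN_SPECS",
    "JAN_MAYEN_MIXTURE",
    "GULLY_SPECS",
    "GULLY_MIXTURE",
    "ABSTRACT_FORAGING_SPECS",
    "DEFAULT_ISOTOPE_GROUPS",
    "ZOOPLANKTON_BASELINES",
]

DEG = np.pi / 180.0
MIN_BOTTOM_S = 90.0  # physical floor for a U-dive bottom phase


@dataclass(frozen=True)
class DiveTypeSpec:
    """Statistical description of one dive type.

    Depth in metres, duration in minutes, rates in m s^-1.  ``p_foraging``
    is the probability that the bottom phase is "active" (high roll
    variance, clicking); ``gyration_rate`` is the expected number of
    injected gyration events per dive, split evenly between descent-roll
    and ascent-heading events.
    """

    name: str
    depth_mean: float
    depth_sd: float
    duration_mean: float
    duration_sd: float
    ascent_rate_mean: float
    ascent_rate_sd: float
    descent_rate_mean: float
    descent_rate_sd: float
    p_foraging: float = 0.0
    roll_var_active: float = 0.6
    roll_var_quiet: float = 0.15
    head_var_active: float = 0.5
    head_var_quiet: float = 0.1
    gyration_rate: float = 0.0

    def __post_init__(self) -> None:
        for v, label in (
            (self.depth_mean, "depth_mean"),
            (self.duration_mean, "duration_mean"),
            (self.ascent_rate_mean, "ascent_rate_mean"),
            (self.descent_rate_mean, "descent_rate_mean"),
        ):
            if v <= 0:
                raise SpecError(f"{label} must be > 0")
        for v in (self.p_foraging,):
            if not 0.0 <= v <= 1.0:
                raise SpecError("p_foraging must be in [0, 1]")
        for v in (self.roll_var_active, self.roll_var_quiet, self.head_var_active, self.head_var_quiet):
            if not 0.0 <= v <= 1.0:
                raise SpecError("circular-variance levels must be in [0, 1]")
        if not 0.0 <= self.gyration_rate <= 2.0:
            raise SpecError("gyration_rate must be in [0, 2] events per dive")
        transit = self.depth_mean / self.descent_rate_mean + self.depth_mean / self.ascent_rate_mean
        if self.duration_mean * 60.0 < transit + MIN_BOTTOM_S:
            raise SpecError(
                f"{self.name}: mean duration too short for mean depth at mean rates"
            )


# Published per-location dive-type statistics (mean, SD) used as defaults.
JAN_MAYEN_SPECS = (
    DiveTypeSpec("short_shallow", 121.6, 61.9, 8.2, 4.0, 0.7, 0.3, 0.9, 0.5,
                 p_foraging=25 / 165, gyration_rate=0.0),
    DiveTypeSpec("mid_depth", 430.4, 189.6, 20.5, 3.9, 1.0, 0.4, 1.3, 0.4,
                 p_foraging=105 / 167, gyration_rate=0.35),
    DiveTypeSpec("long_deep", 888.8, 407.4, 41.1, 5.7, 0.8, 0.3, 1.4, 0.4,
                 p_foraging=26 / 32, gyration_rate=0.40),
)
JAN_MAYEN_MIXTURE = (165 / 364, 167 / 364, 32 / 364)

GULLY_SPECS = (
    DiveTypeSpec("short_shallow", 171.6, 96.0, 13.9, 7.2, 0.5, 0.2, 0.6, 0.3,
                 p_foraging=18 / 61, gyration_rate=0.0),
    DiveTypeSpec("long_deep", 1188.0, 456.8, 43.6, 6.9, 1.1, 0.4, 1.6, 0.3,
                 p_foraging=14 / 15, gyration_rate=0.08),
)
GULLY_MIXTURE = (61 / 76, 15 / 76)

# Alternative scenario: foraging-dive depths as quoted in the study summary.
ABSTRACT_FORAGING_SPECS = (
    DiveTypeSpec("mid_depth", 537.0, 135.0, 22.0, 4.0, 1.0, 0.4, 1.3, 0.4, p_foraging=1.0),
    DiveTypeSpec("long_deep_jm", 967.0, 394.0, 41.0, 6.0, 0.8, 0.3, 1.4, 0.4, p_foraging=1.0),
    DiveTypeSpec("long_deep_gully", 1247.0, 411.0, 44.0, 7.0, 1.1, 0.4, 1.6, 0.3, p_foraging=1.0),
)


@dataclass
class TruthDive:
    """Ground truth for one generated dive (times in seconds since tag-on)."""

    index: int
    type_name: str
    start_s: float
    end_s: float
    t_desc_end: float
    t_asc_start: float
    max_depth_m: float
    duration_min: float
    descent_rate_ms: float
    ascent_rate_ms: float
    foraging: bool
    clicking: bool
    roll_var_target: float
    head_var_target: float


@dataclass
class TruthGyration:
    dive_index: int
    phase: str  # descent | ascent
    axis: str  # roll | heading
    start_s: float
    end_s: float
    n_rotations: int
    direction: int


@dataclass
class SimTruth:
    """Everything the generator knows that the analysis must recover."""

    dives: list[TruthDive] = field(default_factory=list)
    gyrations: list[TruthGyration] = field(default_factory=list)
    click_bouts: list[tuple[float, float]] = field(default_factory=list)
    isotope_params: dict | None = None
    angles: dict[str, np.ndarray] | None = None  # generating pitch/roll/heading


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    if sd <= 0:
        return np.full(size, mean) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_dive_parameters(spec: DiveTypeSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-dive (depth, duration, rates) from a spec.

    Truncation at +/-4 SD and at physical floors (45 m depth so every dive
    crosses the 40-m criterion, 0.15 m s^-1 rates, 2 min duration) keeps the
    tails physical.  Durations too short to reach the drawn depth at the
    drawn rates are extended to transit time plus a minimal bottom phase.
    """
    depth = _trunc_normal(rng, spec.depth_mean, spec.depth_sd,
                          max(45.0, spec.depth_mean - 4 * spec.depth_sd),
                          spec.depth_mean + 4 * spec.depth_sd, n)
    dur = _trunc_normal(rng, spec.duration_mean, spec.duration_sd,
                        max(2.0, spec.duration_mean - 4 * spec.duration_sd),
                        spec.duration_mean + 4 * spec.duration_sd, n)
    asc = _trunc_normal(rng, spec.ascent_rate_mean, spec.ascent_rate_sd,
                        max(0.15, spec.ascent_rate_mean - 4 * spec.ascent_rate_sd),
                        spec.ascent_rate_mean + 4 * spec.ascent_rate_sd, n)
    desc = _trunc_normal(rng, spec.descent_rate_mean, spec.descent_rate_sd,
                         max(0.15, spec.descent_rate_mean - 4 * spec.descent_rate_sd),
                         spec.descent_rate_mean + 4 * spec.descent_rate_sd, n)
    depth, dur, asc, desc = (np.atleast_1d(x) for x in (depth, dur, asc, desc))
    # joint feasibility: the drawn duration must accommodate the vertical
    # transit plus a minimal bottom phase.  Cap depth first (keeps every
    # marginal inside its truncation range); only if even the 45-m floor
    # does not fit is the duration extended.
    inv_rate = 1.0 / desc + 1.0 / asc
    depth_cap = np.maximum(45.0, (dur * 60.0 - MIN_BOTTOM_S) / inv_rate)
    depth = np.minimum(depth, depth_cap)
    transit = depth * inv_rate
    dur = np.maximum(dur, (transit + MIN_BOTTOM_S) / 60.0)
    return pd.DataFrame(
        {
            "type": spec.name,
            "max_depth_m": depth,
            "duration_min": dur,
            "ascent_rate_ms": asc,
            "descent_rate_ms": desc,
        }
    )


def _smooth_noise(rng, n, fs, spacing_s):
    """Zero-start, roughly unit-variance smooth process (cubic knot spline)."""
    if n <= 1:
        return np.zeros(n)
    dur = n / fs
    k = max(4, int(np.ceil(dur / spacing_s)) + 3)
    tk = np.linspace(-spacing_s, dur + spacing_s, k)
    yk = rng.standard_normal(k)
    x = CubicSpline(tk, yk)(np.arange(n) / fs)
    return x - x[0]


def _smooth_walk(rng, n, fs, spacing_s, step_sd_rad):
    """Smooth cumulative random walk (for tortuous surface headings)."""
    if n <= 1:
        return np.zeros(n)
    dur = n / fs
    k = max(4, int(np.ceil(dur / spacing_s)) + 3)
    tk = np.linspace(0.0, dur + spacing_s, k)
    yk = np.cumsum(rng.standard_normal(k) * step_sd_rad)
    x = CubicSpline(tk, yk)(np.arange(n) / fs)
    return x - x[0]


def _calibrated_process(rng, n, fs, base, target_var, spacing_s=4.0):
    """Smooth wrapped process whose empirical circular variance equals target.

    A smooth zero-start process is scaled by the root of a bracketing search
    so that ``circular_variance(base + s*xi)`` matches ``target_var``; this
    makes the generator's variance contract exact rather than asymptotic.
    """
    if n < 2 or target_var <= 1e-6:
        return np.full(n, base)
    xi = _smooth_noise(rng, n, fs, spacing_s)
    if np.std(xi) < 1e-9:
        return np.full(n, base)

    def objective(s):
        return circular_variance(base + s * xi) - target_var

    hi = 1.0
    while objective(hi) < 0 and hi < 64.0:
        hi *= 2.0
    if objective(hi) < 0:
        s_opt = hi
    else:
        s_opt = brentq(objective, 0.0, hi, xtol=1e-6)
    return base + s_opt * xi


def inject_gyration(
    angles: np.ndarray,
    start: int,
    n_rotations: int,
    direction: int,
    samples_per_rotation: int,
    axis: str = "roll",
) -> tuple[np.ndarray, dict]:
    """Superimpose ``n_rotations`` continuous full turns on an angle segment.

    The rotation ramp is *added* to the existing angle series over
    ``n_rotations * samples_per_rotation`` samples; because whole turns are
    multiples of 360 deg, the wrapped series is continuous at both ends.
    Returns the modified (wrapped) copy and an event record with sample
    indices.
    """
    if n_rotations < 2:
        raise SpecError("a gyration needs a minimum of two continuous rotations")
    if direction not in (-1, 1):
        raise SpecError("direction must be +1 or -1")
    length = n_rotations * samples_per_rotation
    if start < 0 or start + length > len(angles):
        raise SpecError("segment too short for the requested rotations")
    out = np.asarray(angles, dtype=float).copy()
    ramp = np.zeros(len(out))
    idx = np.arange(len(out))
    rel = np.clip((idx - start) / length, 0.0, 1.0)
    ramp = direction * 2.0 * np.pi * n_rotations * rel
    out = wrap_angle(out + ramp)
    event = {
        "axis": axis,
        "start": int(start),
        "end": int(start + length),
        "n_rotations": int(n_rotations),
        "direction": int(direction),
    }
    return out, event


# ---------------------------------------------------------------------------
# deployment synthesis
# ---------------------------------------------------------------------------

_SURF_DEPTH = 0.4  # resting logger depth, m


def _surface_chunk(rng, n, fs, h0):
    depth = np.clip(_SURF_DEPTH + 0.15 * _smooth_noise(rng, n, fs, 8.0), 0.05, 3.0)
    pitch = 2.0 * DEG * _smooth_noise(rng, n, fs, 6.0)
    roll = 2.0 * DEG * _smooth_noise(rng, n, fs, 6.0)
    heading = h0 + _smooth_walk(rng, n, fs, 5.0, 40.0 * DEG)
    return depth, pitch, roll, heading


def _dive_chunk(rng, fs, params, spec, h0, surface_band_m=5.0):
    """Build one U-shaped dive; returns arrays plus relative ground truth."""
    D = float(params["max_depth_m"])
    dur_s = float(params["duration_min"]) * 60.0
    rd = float(params["descent_rate_ms"])
    ra = float(params["ascent_rate_ms"])
    d0 = _SURF_DEPTH

    n1 = max(2, int(round((D - d0) / rd * fs)))
    n3 = max(2, int(round((D - d0) / ra * fs)))
    t_desc, t_asc = n1 / fs, n3 / fs
    rd_eff = (D - d0) / t_desc
    ra_eff = (D - d0) / t_asc
    n2 = max(int(round(MIN_BOTTOM_S * fs)), int(round(dur_s * fs)) - n1 - n3)
    L = n2 / fs

    P_d = rng.uniform(30.0, 60.0) * DEG
    P_a = rng.uniform(30.0, 60.0) * DEG
    A = min(P_d, P_a, 20.0 * DEG)
    t5 = (surface_band_m - d0) / rd_eff
    ramp_in = min(3.0, 0.8 * t5)
    r1 = min(8.0, (t_desc - ramp_in) / 2.5, L / 4.0, t_asc / 4.0)
    r1 = max(r1, 2.0 / fs)

    # depth -----------------------------------------------------------------
    u1 = np.arange(n1) / fs
    depth_desc = d0 + rd_eff * u1
    u2 = np.arange(n2) / fs
    bumps = max(1, int(round(L / 90.0)))
    amp = max(0.0, min(6.0, D - 43.0))
    depth_bot = D - amp * (1.0 - np.cos(2.0 * np.pi * bumps * u2 / L)) / 2.0
    u3 = np.arange(n3) / fs
    depth_asc = D - ra_eff * u3

    # pitch -----------------------------------------------------------------
    p_desc = np.full(n1, -P_d)
    m = u1 < ramp_in
    p_desc[m] = -P_d * u1[m] / ramp_in
    m = (u1 >= t_desc - 2 * r1) & (u1 < t_desc - r1)
    p_desc[m] = -P_d + (P_d - A) * (u1[m] - (t_desc - 2 * r1)) / r1
    m = u1 >= t_desc - r1
    p_desc[m] = -A * (t_desc - u1[m]) / r1

    p_bot = A * np.cos(np.pi * np.clip((u2 - r1) / max(L - 2 * r1, 1e-9), 0.0, 1.0))
    m = u2 < r1
    p_bot[m] = A * u2[m] / r1
    m = u2 > L - r1
    p_bot[m] = -A * (L - u2[m]) / r1

    ramp_out = max(2.0 / fs, min(2.0, 0.8 * (surface_band_m - d0) / ra_eff))
    p_asc = np.full(n3, P_a)
    m = u3 < r1
    p_asc[m] = A * u3[m] / r1
    m = (u3 >= r1) & (u3 < 2 * r1)
    p_asc[m] = A + (P_a - A) * (u3[m] - r1) / r1
    m = u3 > t_asc - ramp_out
    p_asc[m] = P_a * (t_asc - u3[m]) / ramp_out

    # roll / heading --------------------------------------------------------
    foraging = rng.random() < spec.p_foraging
    roll_target = spec.roll_var_active if foraging else spec.roll_var_quiet
    head_target = spec.head_var_active if foraging else spec.head_var_quiet

    roll_desc = 3.0 * DEG * _smooth_noise(rng, n1, fs, 6.0)
    head_desc = h0 + 5.0 * DEG * _smooth_noise(rng, n1, fs, 8.0)
    roll_bot = _calibrated_process(rng, n2, fs, float(roll_desc[-1]), roll_target)
    head_bot = _calibrated_process(rng, n2, fs, float(head_desc[-1]), head_target)
    r_end = float(wrap_angle(roll_bot[-1]))
    roll_asc = r_end * np.exp(-u3 / 5.0) + 3.0 * DEG * _smooth_noise(rng, n3, fs, 6.0)
    h_end = float(head_bot[-1])
    head_asc = h_end + 5.0 * DEG * _smooth_noise(rng, n3, fs, 8.0)

    # gyrations -------------------------------------------------------------
    spr = max(4, int(round(fs * 360.0 / 40.0)))  # 40 deg/s rotation rate
    events = []
    if spec.gyration_rate > 0:
        margin = max(int(2 * r1 * fs), int(2 * fs))
        if rng.random() < spec.gyration_rate / 2.0:
            n_rot = 2 + int(rng.poisson(0.8))
            while n_rot >= 2 and n_rot * spr + 2 * margin > n1:
                n_rot -= 1
            if n_rot >= 2:
                start = int(rng.integers(margin, n1 - n_rot * spr - margin + 1))
                roll_desc, ev = inject_gyration(roll_desc, start, n_rot,
                                                int(rng.choice((-1, 1))), spr, "roll")
                ev["phase"] = "descent"
                events.append(ev)
        if rng.random() < spec.gyration_rate / 2.0:
            n_rot = 2 + int(rng.poisson(0.8))
            while n_rot >= 2 and n_rot * spr + 2 * margin > n3:
                n_rot -= 1
            if n_rot >= 2:
                start = int(rng.integers(margin, n3 - n_rot * spr - margin + 1))
                head_asc, ev = inject_gyration(head_asc, start, n_rot,
                                               int(rng.choice((-1, 1))), spr, "heading")
                ev["phase"] = "ascent"
                events.append(ev)

    depth = np.concatenate([depth_desc, depth_bot, depth_asc])
    pitch = np.concatenate([p_desc, p_bot, p_asc])
    roll = np.concatenate([roll_desc, roll_bot, roll_asc])
    heading = np.concatenate([head_desc, head_bot, head_asc])

    truth = {
        "t_in": t5,
        "t_out": (n1 + n2) / fs + (D - surface_band_m) / ra_eff,
        "t1": t_desc,
        "t2": t_desc + L,
        "max_depth": D,
        "descent_rate": rd_eff,
        "ascent_rate": ra_eff,
        "foraging": foraging,
        "roll_target": roll_target,
        "head_target": head_target,
        "n_samples": n1 + n2 + n3,
        "events": events,
    }
    return depth, pitch, roll, heading, truth


def _sensors_from_angles(pitch, roll, heading, inclination_rad):
    """Gravity and earth-field vectors in the sensor frame (inverse model).

    Built from explicit rotation matrices (body NED frame, aerospace order
    heading-pitch-roll) and therefore an independent code path from the
    closed-form estimator in :mod:`deepdive.kinematics`.
    """
    sp, cp = np.sin(pitch), np.cos(pitch)
    sr, cr = np.sin(roll), np.cos(roll)
    accel = GRAVITY * np.column_stack([sp, cp * sr, cp * cr])
    cd, sd = np.cos(inclination_rad), np.sin(inclination_rad)
    sh, ch = np.sin(heading), np.cos(heading)
    # m2 = Rz(-psi) @ (cd, 0, sd); m1 = Ry(-theta) @ m2; m0 = Rx(-phi) @ m1
    m2x, m2y, m2z = cd * ch, -cd * sh, np.full_like(sh, sd)
    m1x = cp * m2x - sp * m2z
    m1y = m2y
    m1z = sp * m2x + cp * m2z
    m0x = m1x
    m0y = cr * m1y + sr * m1z
    m0z = -sr * m1y + cr * m1z
    mag = np.column_stack([m0x, -m0y, -m0z])  # body NED -> sensor frame
    return accel, mag


def simulate_deployment(
    specs,
    mixture,
    n_dives: int,
    fs: float = 32.0,
    seed: int | None = None,
    *,
    deployment_id: str = "sim",
    location: str = "Sim",
    lead_in_s: float = 120.0,
    surface_median_s: float = 480.0,
    surface_log_sd: float = 0.5,
    noise: float = 1.0,
    mag_inclination_deg: float = 75.0,
    with_clicks: bool = True,
    click_mismatch_p: float = 0.0,
    jerk_transients: bool = True,
    keep_angles: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[TagSeries, SimTruth]:
    """Generate one tag deployment plus its ground truth.

    ``noise`` scales the sensor noise floors (0.15 m depth, 0.1 m s^-2
    accel, 0.003 mag); ``noise=0`` gives analytically clean streams for
    round-trip tests.  ``jerk_transients=False`` drops the prey-capture
    acceleration spikes, leaving gravity-only (orientation-recoverable)
    acceleration.  ``with_clicks=False`` emulates a no-audio tag
    (``click_bouts`` is ``None`` rather than empty).
    """
    specs = tuple(specs)
    mixture = np.asarray(mixture, dtype=float)
    if len(specs) != len(mixture):
        raise SpecError("specs and mixture lengths differ")
    if abs(mixture.sum() - 1.0) > 1e-9 or np.any(mixture < 0):
        raise SpecError("mixture must be non-negative and sum to 1")
    if n_dives < 1:
        raise SpecError("n_dives must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    plan_rng, angle_rng, noise_rng = rng.spawn(3)

    types = plan_rng.choice(len(specs), size=n_dives, p=mixture)
    plans = [draw_dive_parameters(specs[k], 1, plan_rng).iloc[0] for k in types]
    surf_mu = np.log(surface_median_s)
    surf_durs = np.r_[lead_in_s, plan_rng.lognormal(surf_mu, surface_log_sd, size=n_dives)]

    chunks_d, chunks_p, chunks_r, chunks_h = [], [], [], []
    truth = SimTruth()
    active_spans: list[tuple[int, int]] = []  # bottom spans for jerk transients
    offset = 0  # samples so far
    h_last = float(angle_rng.uniform(-np.pi, np.pi))

    for i in range(n_dives + 1):
        n_surf = max(2, int(round(surf_durs[i] * fs)))
        d, p, r, h = _surface_chunk(angle_rng, n_surf, fs, h_last)
        chunks_d.append(d); chunks_p.append(p); chunks_r.append(r); chunks_h.append(h)
        h_last = float(h[-1])
        offset += n_surf
        if i == n_dives:
            break
        spec = specs[types[i]]
        d, p, r, h, tr = _dive_chunk(angle_rng, fs, plans[i], spec, h_last)
        chunks_d.append(d); chunks_p.append(p); chunks_r.append(r); chunks_h.append(h)
        h_last = float(h[-1])
        t_off = offset / fs
        clicking = tr["foraging"]
        if click_mismatch_p > 0 and plan_rng.random() < click_mismatch_p:
            clicking = not clicking
        truth.dives.append(
            TruthDive(
                index=i,
                type_name=spec.name,
                start_s=t_off + tr["t_in"],
                end_s=t_off + tr["t_out"],
                t_desc_end=t_off + tr["t1"],
                t_asc_start=t_off + tr["t2"],
                max_depth_m=tr["max_depth"],
                duration_min=(tr["t_out"] - tr["t_in"]) / 60.0,
                descent_rate_ms=tr["descent_rate"],
                ascent_rate_ms=tr["ascent_rate"],
                foraging=tr["foraging"],
                clicking=clicking,
                roll_var_target=tr["roll_target"],
                head_var_target=tr["head_target"],
            )
        )
        for ev in tr["events"]:
            base = offset if ev["phase"] == "descent" else offset + int(round(tr["t2"] * fs))
            # ascent events were recorded relative to the ascent chunk
            if ev["phase"] == "ascent":
                base = offset + int(round(tr["t2"] * fs))
            truth.gyrations.append(
                TruthGyration(
                    dive_index=i,
                    phase=ev["phase"],
                    axis=ev["axis"],
                    start_s=(base + ev["start"]) / fs,
                    end_s=(base + ev["end"]) / fs,
                    n_rotations=ev["n_rotations"],
                    direction=ev["direction"],
                )
            )
        if clicking:
            b0, b1 = t_off + tr["t1"], t_off + tr["t2"]
            if b1 - b0 > 8.0:
                b0, b1 = b0 + 2.0, b1 - 2.0
            truth.click_bouts.append((b0, b1))
        if tr["foraging"]:
            i_b0 = offset + int(round(tr["t1"] * fs))
            i_b1 = offset + int(round(tr["t2"] * fs))
            active_spans.append((i_b0, i_b1))
        offset += tr["n_samples"]

    depth = np.concatenate(chunks_d)
    pitch = np.concatenate(chunks_p)
    roll = wrap_angle(np.concatenate(chunks_r))
    heading = wrap_angle(np.concatenate(chunks_h))
    n = len(depth)
    t = np.arange(n) / fs
    if keep_angles:
        truth.angles = {"pitch": pitch.copy(), "roll": roll.copy(), "heading": heading.copy()}

    accel, mag = _sensors_from_angles(pitch, roll, heading, mag_inclination_deg * DEG)

    # sparse high-jerk transients in active bottom phases (prey-capture
    # proxy); kept >= 3 s clear of the phase boundaries so smoothed-pitch
    # phase detection is not perturbed at the crossings
    for i_b0, i_b1 in active_spans if jerk_transients else ():
        margin = int(round(3.0 * fs))
        dur = (i_b1 - i_b0) / fs
        n_spikes = noise_rng.poisson(0.15 * dur)
        half = max(2, int(round(0.125 * fs)))
        if i_b1 - i_b0 <= 2 * (margin + half):
            continue
        for _ in range(n_spikes):
            c = int(noise_rng.integers(i_b0 + margin + half, i_b1 - margin - half))
            direction = noise_rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            amp = noise_rng.uniform(2.0, 6.0)
            wave = amp * np.sin(np.linspace(0.0, np.pi, 2 * half))
            accel[c - half : c + half] += wave[:, None] * direction[None, :]

    if noise > 0:
        depth = depth + noise * 0.15 * noise_rng.standard_normal(n)
        depth = np.clip(depth, -0.9, None)
        accel = accel + noise * 0.10 * noise_rng.standard_normal((n, 3))
        mag = mag + noise * 0.003 * noise_rng.standard_normal((n, 3))

    series = TagSeries(
        deployment_id=deployment_id,
        location=location,
        fs=fs,
        t=t,
        depth=depth,
        accel=accel,
        mag=mag,
        click_bouts=list(truth.click_bouts) if with_clicks else None,
    )
    return series, truth


# ---------------------------------------------------------------------------
# isotope samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeGroupSpec:
    """Bivariate-normal (d13C, d15N) group with sampling metadata."""

    location: str
    year: int
    n: int
    mean: tuple[float, float]  # (d13C, d15N) in permil
    cov: tuple[tuple[float, float], tuple[float, float]]
    sex_ratio_f: float = 0.6


def _diag(sd_c: float, sd_n: float):
    return ((sd_c**2, 0.0), (0.0, sd_n**2))


# Published per-year skin-sample statistics (uncorrected d13C / d15N).
DEFAULT_ISOTOPE_GROUPS = (
    IsotopeGroupSpec("JanMayen", 2014, 12, (-18.55, 14.96), _diag(0.18, 0.36), 8 / 12),
    IsotopeGroupSpec("JanMayen", 2016, 6, (-18.67, 15.17), _diag(0.19, 0.31), 5 / 6),
    IsotopeGroupSpec("ScotianShelf", 1997, 16, (-17.38, 15.23), _diag(0.40, 0.32), 12 / 16),
    IsotopeGroupSpec("ScotianShelf", 2013, 7, (-16.91, 15.39), _diag(0.65, 0.18), 2 / 7),
    IsotopeGroupSpec("ScotianShelf", 2015, 7, (-16.79, 15.60), _diag(1.03, 0.89), 4 / 7),
    IsotopeGroupSpec("ScotianShelf", 2016, 11, (-17.15, 15.58), _diag(0.64, 0.24), 5 / 11),
)

# Mean zooplankton baseline (d13C, d15N) per ecoregion.
ZOOPLANKTON_BASELINES = {
    "JanMayen": (-23.61, 6.47),
    "ScotianShelf": (-21.89, 5.28),
}


def simulate_isotopes(
    groups=DEFAULT_ISOTOPE_GROUPS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw independent bivariate-normal isotope samples per group.

    Returns a tidy frame ``sample_id, location, year, sex, d13C, d15N,
    corrected`` (``corrected`` is False: offsets are applied downstream).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        if g.n < 3:
            raise SpecError("need n >= 3 samples per group")
        cov = np.asarray(g.cov, dtype=float)
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise SpecError(f"{g.location} {g.year}: covariance not positive definite")
        draws = rng.multivariate_normal(np.asarray(g.mean, float), cov, size=g.n)
        sexes = np.where(rng.random(g.n) < g.sex_ratio_f, "F", "M")
        for j in range(g.n):
            rows.append(
                {
                    "sample_id": f"{g.location}_{g.year}_{j:03d}",
                    "location": g.location,
                    "year": g.year,
                    "sex": sexes[j],
                    "d13C": draws[j, 0],
                    "d15N": draws[j, 1],
                    "corrected": False,
                }
            )
    return pd.DataFrame(rows)
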